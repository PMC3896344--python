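"""Inhomogeneous-Poisson spike-train simulation with stimulus-locked phases.

Generates populations of single-trial spike trains with the statistical
structure the analysis assumes for antennal-lobe responses: a baseline
Poisson rate, stimulus-locked excitation/inhibition phases, a
condition-dependent onset latency, and optional post-stimulus rate tails.
Simulation is by Poisson thinning against the envelope maximum, which is
exact for the bounded piecewise-constant envelopes used here and stable
under a fixed seed.

All profile times are milliseconds relative to stimulus onset; emitted
``SpikeTrain`` objects carry absolute times in seconds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import SpikeTrain


@dataclass(frozen=True)
class SyntheticProfile:
    """Parametric rate envelope driving Poisson spike generation.

    ``phases`` are ``(t_start_ms, t_end_ms, rate_hz)`` intervals relative to
    stimulus onset, before the latency shift; ``onset_latency_ms`` is added
    to every phase boundary.  Outside all (shifted) phases the rate is
    ``baseline_rate``.
    """

    baseline_rate: float
    phases: tuple[tuple[float, float, float], ...] = ()
    onset_latency_ms: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_rate) and self.baseline_rate >= 0):
            raise ValueError("baseline_rate must be finite and >= 0")
        if self.onset_latency_ms < 0:
            raise ValueError("onset_latency_ms must be >= 0")
        phases = tuple(
            (float(a), float(b), float(r)) for a, b, r in self.phases
        )
        for a, b, r in phases:
            if not (b > a):
                raise ValueError(f"phase ({a}, {b}) must have t_end > t_start")
            if not (np.isfinite(r) and r >= 0):
                raise ValueError("phase rates must be finite and >= 0")
        for (_, b0, _), (a1, _, _) in zip(phases, phases[1:]):
            if a1 < b0:
                raise ValueError("phases must be ordered and non-overlapping")
        object.__setattr__(self, "phases", phases)

    @property
    def max_rate(self) -> float:
        return max([self.baseline_rate] + [r for _, _, r in self.phases])

    def shifted_phases(self) -> tuple[tuple[float, float, float], ...]:
        d = self.onset_latency_ms
        return tuple((a + d, b + d, r) for a, b, r in self.phases)

    def with_latency(self, latency_ms: float) -> "SyntheticProfile":
        return replace(self, onset_latency_ms=latency_ms)


def rate_envelope(profile: SyntheticProfile, t_ms):
    """Evaluate the latency-shifted rate envelope (Hz) at time(s) ``t_ms``.

    Phase membership is half-open, ``t_start <= t < t_end``, so abutting
    phases partition time without double counting.
    """
    t = np.asarray(t_ms, dtype=float)
    rate = np.full(t.shape, profile.baseline_rate)
    for a, b, r in profile.shifted_phases():
        rate[(t >= a) & (t < b)] = r
    if np.ndim(t_ms) == 0:
        return float(rate)
    return rate


# -- presets mirroring the stereotyped stimulus-locked response types -------
# Rates are illustrative defaults, not estimates from any recording.

def biphasic_profile(label: str = "", latency_ms: float = 175.0,
                     baseline: float = 5.0, excited_rate: float = 30.0,
                     inhibited_rate: float = 1.0) -> SyntheticProfile:
    """Excitation (30 Hz, 200 ms) followed by suppression (1 Hz, 300 ms)."""
    return SyntheticProfile(
        baseline_rate=baseline,
        phases=((0.0, 200.0, excited_rate), (200.0, 500.0, inhibited_rate)),
        onset_latency_ms=latency_ms,
        label=label,
    )


def excited_profile(label: str = "", latency_ms: float = 175.0,
                    baseline: float = 5.0, rate: float = 30.0,
                    duration_ms: float = 500.0) -> SyntheticProfile:
    """Sustained rate increase for the stimulus period."""
    return SyntheticProfile(
        baseline_rate=baseline,
        phases=((0.0, duration_ms, rate),),
        onset_latency_ms=latency_ms,
        label=label,
    )


def inhibited_profile(label: str = "", latency_ms: float = 175.0,
                      baseline: float = 5.0, rate: float = 1.0,
                      duration_ms: float = 500.0) -> SyntheticProfile:
    """Suppression below baseline for the stimulus period."""
    return SyntheticProfile(
        baseline_rate=baseline,
        phases=((0.0, duration_ms, rate),),
        onset_latency_ms=latency_ms,
        label=label,
    )


def with_tail(profile: SyntheticProfile, t_start_ms: float, t_end_ms: float,
              rate: float) -> SyntheticProfile:
    """Append a post-stimulus elevated-rate tail (odor-trace-like)."""
    return replace(profile, phases=profile.phases + ((t_start_ms, t_end_ms, rate),))


@dataclass(frozen=True)
class SyntheticCohort:
    """Trial-generation plan: one profile per condition, n trials each.

    ``recording_span_ms`` (relative to stimulus onset) must cover both the
    pre-stimulus control window and the response window, with margin for
    kernel tails.
    """

    profiles: dict[str, SyntheticProfile]
    n_trials: int
    seed: int
    recording_span_ms: tuple[float, float] = (-1600.0, 1600.0)
    stimulus_onset_s: float = 2.0
    stimulus_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 per condition")
        lo, hi = self.recording_span_ms
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("recording_span_ms must be a finite interval")


def _trial_seed(cohort_seed: int, condition: str, trial_index: int) -> np.random.Generator:
    # crc32 keys the condition label into the seed stream deterministically
    # across platforms (builtin hash() is salted per process).
    ss = np.random.SeedSequence(
        [int(cohort_seed), zlib.crc32(condition.encode("utf-8")), int(trial_index)]
    )
    return np.random.default_rng(ss)


def simulate_trial(profile: SyntheticProfile,
                   span_ms: tuple[float, float],
                   seed,
                   *,
                   stimulus_onset_s: float = 2.0,
                   stimulus_duration_s: float = 0.5,
                   neuron_id: str = "sim",
                   trial_id: str = "0",
                   response_type: str = "",
                   morph_type: str = "",
                   dead_time_ms: float = 0.0) -> SpikeTrain:
    """Draw one spike train from an inhomogeneous Poisson process.

    Candidate spikes are drawn homogeneously at the envelope maximum over
    ``span_ms`` and thinned by the ratio envelope/max (exact for bounded
    envelopes).  ``seed`` may be an integer or a ``numpy`` Generator.
    ``dead_time_ms > 0`` additionally discards spikes closer than that to
    the previous retained spike (off by default: the analysis makes no
    refractoriness assumption).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = float(span_ms[0]), float(span_ms[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("span_ms must be a finite interval")
    lam_max = profile.max_rate
    times_ms = np.empty(0)
    if lam_max > 0:
        duration_s = (hi - lo) / 1000.0
        n_cand = rng.poisson(lam_max * duration_s)
        cand = np.sort(rng.uniform(lo, hi, size=n_cand))
        accept = rng.uniform(0.0, 1.0, size=n_cand) * lam_max < rate_envelope(profile, cand)
        times_ms = cand[accept]
        if dead_time_ms > 0 and times_ms.size:
            kept = [times_ms[0]]
            for t in times_ms[1:]:
                if t - kept[-1] >= dead_time_ms:
                    kept.append(t)
            times_ms = np.asarray(kept)
    return SpikeTrain(
        spike_times=stimulus_onset_s + times_ms / 1000.0,
        neuron_id=neuron_id,
        trial_id=trial_id,
        condition=profile.label,
        stimulus_onset=stimulus_onset_s,
        stimulus_offset=stimulus_onset_s + stimulus_duration_s,
        response_type=response_type,
        morph_type=morph_type,
    )


def simulate_cohort(cohort: SyntheticCohort,
                    *,
                    response_type: str = "",
                    morph_type: str = "") -> dict[str, list[SpikeTrain]]:
    """Simulate ``n_trials`` trains per condition, grouped by condition.

    Per-trial generators are derived deterministically from the cohort seed,
    the condition label and the trial index, so any sub-stream is
    reproducible independently of generation order.
    """
    out: dict[str, list[SpikeTrain]] = {}
    for condition, profile in cohort.profiles.items():
        prof = profile if profile.label == condition else replace(profile, label=condition)
        trains = []
        for i in range(cohort.n_trials):
            rng = _trial_seed(cohort.seed, condition, i)
            trains.append(simulate_trial(
                prof, cohort.recording_span_ms, rng,
                stimulus_onset_s=cohort.stimulus_onset_s,
                stimulus_duration_s=cohort.stimulus_duration_s,
                neuron_id=f"sim-{condition}", trial_id=str(i),
                response_type=response_type, morph_type=morph_type,
            ))
        out[condition] = trains
    return out
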