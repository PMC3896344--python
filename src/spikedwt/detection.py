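"""Spike detection from raw voltage traces by amplitude thresholding.

Two variants: intracellular (threshold at half the maximum peak amplitude)
and juxtacellular (high-pass filter first, threshold at one third of the
maximum peak amplitude).  Peak amplitude is measured from the median of the
processed trace, a robust baseline under slow drift; each above-threshold
excursion is refined to its local maximum so that one time is reported per
spike, and lesser peaks within the refractory guard of a larger accepted
one are suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import SpikeTrain


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane potential with stimulus timing.

    ``samples`` in mV, ``sampling_rate`` in Hz, ``t0`` the absolute time of
    the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    stimulus_onset: float = 0.0
    stimulus_offset: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.samples, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.stimulus_onset < self.stimulus_offset:
            raise ValueError("stimulus_onset must precede stimulus_offset")
        object.__setattr__(self, "samples", v)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholding parameters.

    threshold_fraction : fraction of the maximum peak amplitude (measured
        from the median baseline) at which spikes are detected; 0.5 for the
        intracellular variant, 1/3 for the juxtacellular one.
    highpass_cutoff : optional high-pass corner (Hz) applied before
        thresholding (the juxtacellular variant); None disables filtering.
    min_separation_ms : refractory guard; crossings closer than this to the
        previous accepted spike are discarded.
    threshold_mv : optional absolute threshold override (mV above the median
        baseline), for traces where the fraction rule needs manual tuning.
    """

    threshold_fraction: float = 0.5
    highpass_cutoff: float | None = None
    min_separation_ms: float = 2.0
    threshold_mv: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.min_separation_ms < 0:
            raise ValueError("min_separation_ms must be >= 0")


JUXTACELLULAR = DetectionConfig(threshold_fraction=1.0 / 3.0, highpass_cutoff=100.0)


def highpass_filter(trace: VoltageTrace, cutoff: float, order: int = 2) -> VoltageTrace:
    """Zero-phase Butterworth high-pass; length and timebase unchanged."""
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, {nyquist} Hz); got {cutoff} Hz"
        )
    sos = butter(order, cutoff, btype="highpass", fs=trace.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, trace.samples)
    return VoltageTrace(filtered, trace.sampling_rate, trace.t0,
                        trace.stimulus_onset, trace.stimulus_offset)


def detect_spikes(trace: VoltageTrace, cfg: DetectionConfig = DetectionConfig(),
                  **train_meta) -> SpikeTrain:
    """Threshold-crossing spike detection.

    The threshold is ``cfg.threshold_fraction`` times the maximum peak
    amplitude of the (optionally high-pass-filtered) trace, measured from
    its median; each above-threshold excursion contributes the time of its
    local maximum.  Extra keyword arguments populate the resulting
    ``SpikeTrain`` metadata.
    """
    proc = trace
    if cfg.highpass_cutoff is not None:
        proc = highpass_filter(trace, cfg.highpass_cutoff)
    v = proc.samples - np.median(proc.samples)
    peak = v.max()
    if peak <= 0:
        warnings.warn("flat trace: no samples above baseline, returning "
                      "empty spike train", stacklevel=2)
        return _make_train(np.empty(0), trace, train_meta)
    threshold = cfg.threshold_mv if cfg.threshold_mv is not None \
        else cfg.threshold_fraction * peak

    # each above-threshold excursion is refined to its local maxima; the
    # refractory guard then suppresses lesser peaks within min_separation
    # of a larger accepted one (amplitude-ordered, so raising the
    # threshold can only remove spikes, never add them)
    peaks, _ = find_peaks(v, height=threshold)
    times = proc.times
    min_sep_s = cfg.min_separation_ms / 1000.0
    accepted: list[int] = []
    for i in peaks[np.argsort(-v[peaks], kind="stable")]:
        if all(abs(times[i] - times[j]) >= min_sep_s for j in accepted):
            accepted.append(int(i))
    return _make_train(times[sorted(accepted)], trace, train_meta)


def _make_train(spike_times: np.ndarray, trace: VoltageTrace,
                meta: dict) -> SpikeTrain:
    defaults = dict(neuron_id="", trial_id="", condition="",
                    response_type="", morph_type="")
    defaults.update(meta)
    return SpikeTrain(spike_times=np.asarray(spike_times, dtype=float),
                      stimulus_onset=trace.stimulus_onset,
                      stimulus_offset=trace.stimulus_offset, **defaults)
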