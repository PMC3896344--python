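"""Shared analysis-unit containers: spike trains and analysis windows.

The analysis unit throughout the package is a single trial's spike train
together with the metadata used to form comparison subsets (response type,
morphological type) and the stimulus timing it is aligned to.  Spike times
are stored in absolute seconds; results downstream are reported in
milliseconds relative to the analysis-window start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

RESPONSE_TYPES = ("biphasic", "excited", "inhibited")
MORPH_TYPES = ("PN", "LN", "MGC")


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamped spikes of one trial with condition metadata.

    Parameters
    ----------
    spike_times
        Absolute spike times in seconds, strictly increasing.
    neuron_id, trial_id
        Identifiers of the recorded neuron and the trial.
    condition
        Stimulus-condition label (the grouping variable of comparisons).
    response_type
        One of ``biphasic``, ``excited``, ``inhibited`` (or ``""`` if
        unclassified); used only to form comparison subsets.
    morph_type
        One of ``PN``, ``LN``, ``MGC`` (or ``""``); subset metadata.
    stimulus_onset, stimulus_offset
        Absolute stimulus timing in seconds; the response analysis window
        starts at ``stimulus_onset``.
    """

    spike_times: np.ndarray
    neuron_id: str
    trial_id: str
    condition: str
    stimulus_onset: float
    stimulus_offset: float
    response_type: str = ""
    morph_type: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError(
                f"spike times of trial {self.trial_id!r} (neuron "
                f"{self.neuron_id!r}) are not strictly increasing"
            )
        if not np.all(np.isfinite(times)):
            raise ValueError("spike times must be finite")
        if not self.stimulus_onset < self.stimulus_offset:
            raise ValueError("stimulus_onset must precede stimulus_offset")
        object.__setattr__(self, "spike_times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def times_relative_ms(self) -> np.ndarray:
        """Spike times in ms relative to stimulus onset."""
        return (self.spike_times - self.stimulus_onset) * 1000.0

    def with_times(self, spike_times: Sequence[float]) -> "SpikeTrain":
        return replace(self, spike_times=np.asarray(spike_times, dtype=float))


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window over which rate functions are binned and decomposed.

    ``start`` is absolute (seconds): the stimulus onset for the response
    window, or ``onset - duration`` for the pre-stimulus control window.
    ``n_bins`` must be a power of two no smaller than ``2**levels`` of the
    decomposition it feeds.
    """

    start: float
    duration: float = 1.4
    n_bins: int = 128

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        n = self.n_bins
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError("n_bins must be a power of 2 >= 2")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def bin_width_s(self) -> float:
        return self.duration / self.n_bins

    @property
    def bin_width_ms(self) -> float:
        return 1000.0 * self.duration / self.n_bins

    def bin_edges(self) -> np.ndarray:
        """Absolute edges (s) of the half-open bins [edge_k, edge_{k+1})."""
        return self.start + self.bin_width_s * np.arange(self.n_bins + 1)

    @classmethod
    def response(cls, onset_s: float, duration: float = 1.4,
                 n_bins: int = 128) -> "AnalysisWindow":
        """Window starting at stimulus onset."""
        return cls(start=onset_s, duration=duration, n_bins=n_bins)

    @classmethod
    def control(cls, onset_s: float, duration: float = 1.4,
                n_bins: int = 128) -> "AnalysisWindow":
        """Pre-stimulus window immediately preceding the onset."""
        return cls(start=onset_s - duration, duration=duration, n_bins=n_bins)


def group_by_condition(trains: Sequence[SpikeTrain]) -> dict[str, list[SpikeTrain]]:
    out: dict[str, list[SpikeTrain]] = {}
    for tr in trains:
        out.setdefault(tr.condition, []).append(tr)
    return out
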