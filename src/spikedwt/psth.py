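"""PSTH baseline: fixed-bin spike counts compared with the same statistics.

Peristimulus time histograms with a 50 ms bin (28 bins over the 1.4 s
window at defaults) are the conventional single-resolution alternative to
the wavelet power maps.  Per-trial bin counts are compared between groups
bin by bin with the same Mann-Whitney / Benjamini-Hochberg machinery, so
differences in sensitivity reflect the representation, not the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnalysisWindow, SpikeTrain
from .stats import (ComparisonResult, SignificanceConfig, bh_adjusted,
                    fdr_bh, _family_tests, _min_q_on_grid, marginal_tier)

DEFAULT_PSTH_BIN_MS = 50.0


def psth_counts(train: SpikeTrain, window: AnalysisWindow,
                bin_width_ms: float = DEFAULT_PSTH_BIN_MS) -> np.ndarray:
    """Spike counts in half-open bins [start+(k-1)w, start+kw), k=1..n.

    ``bin_width_ms`` must divide the window duration evenly (28 bins of
    50 ms at defaults).
    """
    n_float = 1000.0 * window.duration / bin_width_ms
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < 1:
        raise ValueError(
            f"bin width {bin_width_ms} ms does not divide the "
            f"{window.duration * 1000:g} ms window evenly")
    w_s = bin_width_ms / 1000.0
    idx = np.floor((train.spike_times - window.start) / w_s).astype(int)
    counts = np.zeros(n, dtype=int)
    ok = (idx >= 0) & (idx < n)
    np.add.at(counts, idx[ok], 1)
    return counts


def psth_bin_window(bin_index: int, bin_width_ms: float = DEFAULT_PSTH_BIN_MS) -> tuple[float, float]:
    """Time window (ms rel. window start) of 1-based PSTH bin k."""
    if bin_index < 1:
        raise ValueError("bin_index is 1-based")
    return ((bin_index - 1) * bin_width_ms, bin_index * bin_width_ms)


@dataclass(frozen=True)
class PSTHResult:
    """Per-bin comparison result plus the per-trial count matrices."""

    comparison: ComparisonResult
    counts_a: np.ndarray      # (n_trials_a, n_bins)
    counts_b: np.ndarray
    bin_width_ms: float

    @property
    def table(self) -> pd.DataFrame:
        return self.comparison.table

    def intervals(self, tier: str = "significant") -> list[tuple[float, float]]:
        return self.comparison.intervals(tier)


def compare_psth(group_a: Sequence[SpikeTrain], group_b: Sequence[SpikeTrain],
                 window_a: Sequence[AnalysisWindow] | AnalysisWindow,
                 window_b: Sequence[AnalysisWindow] | AnalysisWindow | None = None,
                 cfg: SignificanceConfig = SignificanceConfig(),
                 bin_width_ms: float = DEFAULT_PSTH_BIN_MS,
                 label_a: str = "A", label_b: str = "B") -> PSTHResult:
    """Per-bin U tests between two trial groups with BH-FDR over all bins.

    ``window_a``/``window_b`` may be a single window (shared by all trials
    of the group) or one per trial (stimulus-aligned per-trial windows).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 trials")
    wins_a = _expand(window_a, len(group_a))
    wins_b = _expand(window_b if window_b is not None else window_a, len(group_b))
    a = np.vstack([psth_counts(t, w, bin_width_ms)
                   for t, w in zip(group_a, wins_a)]).astype(float)
    b = np.vstack([psth_counts(t, w, bin_width_ms)
                   for t, w in zip(group_b, wins_b)]).astype(float)

    u, p = _family_tests(a, b)
    fdr = fdr_bh(p, cfg.q_primary)
    min_q = _min_q_on_grid(bh_adjusted(p), cfg)
    med_diff = np.median(a, axis=0) - np.median(b, axis=0)

    n_bins = a.shape[1]
    starts = np.arange(n_bins) * bin_width_ms
    table = pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "t_start_ms": starts,
        "t_end_ms": starts + bin_width_ms,
        "U": u,
        "p": p,
        "min_q": min_q,
        "tier": np.where(fdr.rejected, "significant", "none"),
        "direction": np.sign(med_diff).astype(int),
    })
    comp = ComparisonResult(table=table, crit_p=fdr.crit_p,
                            step_threshold=fdr.step_threshold, cfg=cfg,
                            label_a=label_a, label_b=label_b)
    return PSTHResult(comparison=comp, counts_a=a.astype(int),
                      counts_b=b.astype(int), bin_width_ms=bin_width_ms)


def psth_marginal_tier(result: PSTHResult, control: PSTHResult,
                       cfg: SignificanceConfig | None = None) -> PSTHResult:
    """Marginal-tier assignment for PSTH bins, as for wavelet coefficients."""
    comp = marginal_tier(result.comparison, control.comparison, cfg)
    return replace(result, comparison=comp)


def _expand(window, n: int) -> list[AnalysisWindow]:
    if isinstance(window, AnalysisWindow):
        return [window] * n
    wins = list(window)
    if len(wins) != n:
        raise ValueError("need one window per trial")
    return wins
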