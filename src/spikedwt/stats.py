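"""Group comparison of time-frequency power maps with FDR control.

Corresponding squared DWT coefficients are compared between two stimulus
conditions across all trials with a two-sided Mann-Whitney U test, one test
per coefficient; the family of all coefficients of one comparison is
corrected with the Benjamini-Hochberg step-up.

Two significance tiers mirror the analysis this package implements:

* primary ("significant"): uncorrected p below the critical p realized by
  BH at FDR level ``q_primary`` (default 0.10);
* marginal: the minimal rejecting q lies strictly between ``q_primary`` and
  ``q_marginal_max`` (default 0.25), the pre-stimulus control family shows
  zero rejections at that same q, and the coefficient's time window is not
  already covered by a primary-tier interval.

The minimal rejecting q per coefficient is found by scanning a q grid
(default step 0.01), which by the step-up's monotonicity equals the BH
adjusted p-value rounded up to the grid.

Sample unit is the single trial, pooled across all neurons of a subset;
comparisons are only meaningful within a subset (same response type and
morphological type).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .wavelet import CoefficientPowerMap

__all__ = [
    "SignificanceConfig", "FDRResult", "ComparisonResult",
    "mann_whitney_u", "fdr_bh", "bh_adjusted",
    "compare_coefficients", "marginal_tier", "shuffle_control",
    "merge_intervals", "significant_duration",
]


@dataclass(frozen=True)
class SignificanceConfig:
    q_primary: float = 0.10
    q_marginal_max: float = 0.25
    q_grid_step: float = 0.01
    n_shuffles: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_primary < self.q_marginal_max <= 1:
            raise ValueError("need 0 < q_primary < q_marginal_max <= 1")
        if not 0 < self.q_grid_step <= self.q_marginal_max:
            raise ValueError("q_grid_step must be in (0, q_marginal_max]")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples of powers.

    Uses exact enumeration when the pooled sample is small (n <= 16) and
    tie-free, otherwise the tie-corrected normal approximation with
    continuity correction.  Returns ``(U, p)`` with U the statistic of the
    first sample.  If every value in both samples is identical the test is
    degenerate and ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return (x.size * y.size / 2.0, 1.0)
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 16) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return (float(res.statistic), float(min(res.pvalue, 1.0)))


@dataclass(frozen=True)
class FDRResult:
    crit_p: float            # largest rejected p (0 if none rejected)
    rejected: np.ndarray     # boolean mask, original order
    n_rejected: int
    step_threshold: float    # k*q/m at the step-up index k (0 if k = 0)


def fdr_bh(pvals: Sequence[float], q: float) -> FDRResult:
    """Benjamini-Hochberg step-up over one family of p-values.

    Sorts the family, finds the largest k with ``p(k) <= k*q/m``, rejects
    those k hypotheses; ``crit_p`` is the largest rejected p-value.  Both
    the realized crit_p and the linear step threshold ``k*q/m`` are
    reported, since either convention is used to quote critical values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    below = order <= np.arange(1, m + 1) * q / m
    k = int(np.flatnonzero(below)[-1] + 1) if below.any() else 0
    crit_p = float(order[k - 1]) if k else 0.0
    rejected = p <= crit_p if k else np.zeros(m, dtype=bool)
    return FDRResult(crit_p=crit_p, rejected=rejected,
                     n_rejected=int(rejected.sum()),
                     step_threshold=k * q / m if k else 0.0)


def bh_adjusted(pvals: Sequence[float]) -> np.ndarray:
    """BH adjusted p-values: the minimal q at which each test is rejected."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of (t_start, t_end) intervals: sorted, touching ones merged."""
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _covered(t0: float, t1: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(a <= t0 and t1 <= b for a, b in intervals)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-coefficient test results of one two-group comparison.

    ``table`` columns: level, index, t_start_ms, t_end_ms, f_low_hz,
    f_high_hz, U, p, min_q (BH adjusted p snapped up to the q grid; NaN if
    above ``q_marginal_max``), tier in {significant, marginal, none}, and
    direction, the sign of median(A) - median(B).
    """

    table: pd.DataFrame
    crit_p: float
    step_threshold: float
    cfg: SignificanceConfig
    label_a: str = "A"
    label_b: str = "B"
    control_clean: bool | None = None   # set by marginal_tier

    @property
    def n_primary(self) -> int:
        return int((self.table["tier"] == "significant").sum())

    def intervals(self, tier: str = "significant") -> list[tuple[float, float]]:
        """Merged time intervals (ms) of coefficients in one tier."""
        sub = self.table[self.table["tier"] == tier]
        return merge_intervals(list(zip(sub["t_start_ms"], sub["t_end_ms"])))


def significant_duration(result: ComparisonResult,
                         tiers: Sequence[str] = ("significant",)) -> float:
    """Total length (ms) of the union of merged intervals over tiers."""
    ivs = [iv for t in tiers for iv in result.intervals(t)]
    return float(sum(b - a for a, b in merge_intervals(ivs)))


def _family_tests(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided U tests of matrices a (nA x m) and b (nB x m).

    Vectorizes the asymptotic branch over columns; small tie-free families
    fall back to per-column exact enumeration, and degenerate columns (all
    values identical) get p = 1.
    """
    m = a.shape[1]
    pooled_n = a.shape[0] + b.shape[0]
    u = np.empty(m)
    p = np.empty(m)
    degenerate = np.all(np.vstack([a, b]) == a[0], axis=0)
    if pooled_n <= 16:
        for j in range(m):
            u[j], p[j] = mann_whitney_u(a[:, j], b[:, j])
        return u, p
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True, axis=0)
    u[:] = res.statistic
    p[:] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
    u[degenerate] = a.shape[0] * b.shape[0] / 2.0
    p[degenerate] = 1.0
    return u, p


def _min_q_on_grid(p_adj: np.ndarray, cfg: SignificanceConfig) -> np.ndarray:
    """Smallest grid q at which each coefficient is BH-rejected (NaN if
    none up to q_marginal_max)."""
    step = cfg.q_grid_step
    n_steps = np.ceil(np.round(p_adj / step, 12)) * step
    return np.where(n_steps <= cfg.q_marginal_max + 1e-12, n_steps, np.nan)


def _check_same_geometry(group: Sequence[CoefficientPowerMap],
                         ref: CoefficientPowerMap) -> None:
    for pm in group:
        same = (pm.cfg.levels == ref.cfg.levels
                and pm.cfg.kernel == ref.cfg.kernel
                and pm.cfg.window.n_bins == ref.cfg.window.n_bins
                and math.isclose(pm.cfg.window.duration, ref.cfg.window.duration))
        if not same:
            raise ValueError("all power maps must share the same window "
                             "geometry and DWT configuration")


def compare_coefficients(group_a: Sequence[CoefficientPowerMap],
                         group_b: Sequence[CoefficientPowerMap],
                         cfg: SignificanceConfig = SignificanceConfig(),
                         label_a: str = "A", label_b: str = "B") -> ComparisonResult:
    """One U test per coefficient between two trial groups, BH corrected.

    The FDR family is the complete coefficient set (128 at defaults) of
    this one comparison.  Marginal-tier assignment additionally needs the
    control-period comparison; see :func:`marginal_tier`.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 trials")
    ref = group_a[0]
    _check_same_geometry(group_a, ref)
    _check_same_geometry(group_b, ref)
    a = np.vstack([pm.powers for pm in group_a])
    b = np.vstack([pm.powers for pm in group_b])
    u, p = _family_tests(a, b)

    fdr = fdr_bh(p, cfg.q_primary)
    p_adj = bh_adjusted(p)
    min_q = _min_q_on_grid(p_adj, cfg)
    med_diff = np.median(a, axis=0) - np.median(b, axis=0)

    table = ref.table[["level", "index", "t_start_ms", "t_end_ms",
                       "f_low_hz", "f_high_hz"]].copy()
    table["U"] = u
    table["p"] = p
    table["min_q"] = min_q
    table["tier"] = np.where(fdr.rejected, "significant", "none")
    table["direction"] = np.sign(med_diff).astype(int)
    return ComparisonResult(table=table, crit_p=fdr.crit_p,
                            step_threshold=fdr.step_threshold, cfg=cfg,
                            label_a=label_a, label_b=label_b)


def marginal_tier(result: ComparisonResult, control: ComparisonResult,
                  cfg: SignificanceConfig | None = None) -> ComparisonResult:
    """Assign the marginal tier using the pre-stimulus control comparison.

    A coefficient becomes marginal iff its minimal rejecting q lies in
    (q_primary, q_marginal_max), the control family has zero rejections at
    that same q, and its window is not already inside a primary-tier
    interval.  Also records whether the control family was clean (zero
    rejections) at q_primary.
    """
    if control is None:
        raise ValueError("control-period comparison is required")
    cfg = cfg or result.cfg
    table = result.table.copy()
    primary_iv = result.intervals("significant")
    control_adj = bh_adjusted(control.table["p"].to_numpy())

    for i in table.index[table["tier"] == "none"]:
        mq = table.at[i, "min_q"]
        if not (np.isfinite(mq) and cfg.q_primary < mq < cfg.q_marginal_max):
            continue
        if np.any(control_adj <= mq + 1e-12):
            continue
        if _covered(table.at[i, "t_start_ms"], table.at[i, "t_end_ms"], primary_iv):
            continue
        table.at[i, "tier"] = "marginal"

    clean = not np.any(control_adj <= cfg.q_primary + 1e-12)
    return replace(result, table=table, control_clean=bool(clean))


def shuffle_control(group_a: Sequence[CoefficientPowerMap],
                    group_b: Sequence[CoefficientPowerMap],
                    cfg: SignificanceConfig) -> np.ndarray:
    """Label-shuffle null check: primary-tier rejection count per shuffle.

    Condition labels are permuted over the pooled trials of the subset,
    the full coefficient comparison re-run, and the number of primary-tier
    rejections recorded, for ``cfg.n_shuffles`` permutations seeded by
    ``cfg.seed``.  On real effects this distribution should concentrate at
    zero, mirroring the shuffle control of the analysis.
    """
    if cfg.n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pooled = list(group_a) + list(group_b)
    n_a = len(group_a)
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty(cfg.n_shuffles, dtype=int)
    for s in range(cfg.n_shuffles):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[:n_a]]
        gb = [pooled[i] for i in perm[n_a:]]
        counts[s] = compare_coefficients(ga, gb, cfg).n_primary
    return counts
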