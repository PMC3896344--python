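"""Dyadic Haar wavelet power maps of binned rate functions.

The 128-bin rate vector is decomposed into 4 detail levels plus one
approximation level with an orthonormal Daubechies db1 (Haar) discrete
wavelet transform; every squared coefficient quantifies the power spectral
density of the rate function in one (time window, frequency band) cell.

At the defaults (1.4 s window, 128 bins, 4 levels) the coefficient counts
per level are 64 / 32 / 16 / 8 for details 1-4 and 8 for the approximation
(level 5), with frequency bands 22.86-45.71, 11.43-22.86, 5.71-11.43,
2.86-5.71 and 0-2.86 Hz.  The time window of coefficient ``index`` (1-based,
natural time order) at a level with ``n`` coefficients is
``((index-1) * duration/n, index * duration/n)`` relative to window start.

The orthonormal convention (detail = (a-b)/sqrt(2), approximation =
(a+b)/sqrt(2) per pair) makes total power equal the energy of the binned
vector; with a length-2 filter and dyadic lengths no boundary extension is
ever used, so the choice of extension mode is moot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .core import AnalysisWindow


@dataclass(frozen=True)
class DWTConfig:
    """Decomposition parameters: wavelet family, depth, and the window."""

    window: AnalysisWindow
    levels: int = 4
    kernel: str = "db1"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.window.n_bins % (2 ** self.levels) != 0:
            raise ValueError(
                f"n_bins={self.window.n_bins} not divisible by 2^levels"
            )

    def n_coefficients(self, level: int) -> int:
        """Coefficient count at detail level 1..levels or approximation
        level ``levels + 1``."""
        if not 1 <= level <= self.levels + 1:
            raise ValueError(f"level must be in 1..{self.levels + 1}")
        j = min(level, self.levels)
        return self.window.n_bins // (2 ** j)


def coefficient_time_window(level: int, index: int, cfg: DWTConfig) -> tuple[float, float]:
    """Time window (ms relative to window start) of one coefficient.

    The window duration at each level equals the analyzed time divided by
    the number of coefficients in that level; windows tile the analyzed
    time in natural order, 1-based.
    """
    n = cfg.n_coefficients(level)
    if not 1 <= index <= n:
        raise ValueError(f"index must be in 1..{n} at level {level}")
    delta_ms = 1000.0 * cfg.window.duration / n
    return ((index - 1) * delta_ms, index * delta_ms)


def level_frequency_band(level: int, cfg: DWTConfig) -> tuple[float, float]:
    """Frequency band (Hz) of a decomposition level.

    With Nyquist frequency ``f_N = n_bins / (2 * duration)`` of the binned
    rate, detail level j spans ``(f_N / 2^j, f_N / 2^(j-1))`` and the
    approximation spans ``(0, f_N / 2^levels)``.  Values are exact; round
    to two decimals for display (45.71, 22.86, ... at defaults).
    """
    if not 1 <= level <= cfg.levels + 1:
        raise ValueError(f"level must be in 1..{cfg.levels + 1}")
    f_nyquist = cfg.window.n_bins / (2.0 * cfg.window.duration)
    if level == cfg.levels + 1:
        return (0.0, f_nyquist / 2 ** cfg.levels)
    return (f_nyquist / 2 ** level, f_nyquist / 2 ** (level - 1))


@dataclass(frozen=True)
class CoefficientPowerMap:
    """Squared DWT coefficients of one trial, with time/frequency mapping.

    ``table`` has one row per coefficient: level (1..levels for details,
    levels+1 for the approximation), index (1-based within level), coeff,
    power = coeff**2, t_start_ms / t_end_ms relative to window start, and
    f_low_hz / f_high_hz.
    """

    table: pd.DataFrame
    cfg: DWTConfig

    @property
    def powers(self) -> np.ndarray:
        return self.table["power"].to_numpy()

    @property
    def total_power(self) -> float:
        return float(self.table["power"].sum())

    def level(self, level: int) -> pd.DataFrame:
        return self.table[self.table["level"] == level]


def dwt_decompose(binned: np.ndarray, cfg: DWTConfig) -> CoefficientPowerMap:
    """Orthonormal filter-bank cascade of the binned rate vector.

    Returns all ``n_bins`` coefficients (details at levels 1..levels, the
    approximation at level levels+1) with their squared-coefficient power
    and time/frequency cells.  Energy is preserved: total power equals the
    sum of squared bin values.

    Time-window mapping is exact for the length-2 db1 kernel; for longer
    kernels (accepted for exploration) the windows are nominal.
    """
    x = np.asarray(binned, dtype=float)
    if x.ndim != 1 or x.size != cfg.window.n_bins:
        raise ValueError(f"binned must have length {cfg.window.n_bins}")
    coeffs = pywt.wavedec(x, cfg.kernel, mode="periodization", level=cfg.levels)
    # wavedec order: [approx, detail_levels, ..., detail_1]
    by_level = {cfg.levels + 1: coeffs[0]}
    for j, c in zip(range(cfg.levels, 0, -1), coeffs[1:]):
        by_level[j] = c

    rows = []
    for level in sorted(by_level):
        f_low, f_high = level_frequency_band(level, cfg)
        for i, c in enumerate(by_level[level], start=1):
            t0, t1 = coefficient_time_window(level, i, cfg)
            rows.append((level, i, float(c), float(c) ** 2, t0, t1, f_low, f_high))
    table = pd.DataFrame(rows, columns=[
        "level", "index", "coeff", "power",
        "t_start_ms", "t_end_ms", "f_low_hz", "f_high_hz",
    ])
    return CoefficientPowerMap(table=table, cfg=cfg)


def inverse_dwt(powermap: CoefficientPowerMap) -> np.ndarray:
    """Reconstruct the binned vector from a coefficient map (db1 exact)."""
    cfg = powermap.cfg
    parts = [powermap.level(cfg.levels + 1)["coeff"].to_numpy()]
    for j in range(cfg.levels, 0, -1):
        parts.append(powermap.level(j)["coeff"].to_numpy())
    return pywt.waverec(parts, cfg.kernel, mode="periodization")
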