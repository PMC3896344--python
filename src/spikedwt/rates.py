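"""Instantaneous firing-rate estimation by unit-area Hanning-kernel smoothing.

A spike train is represented as a sum of delta functions and convolved with
a unit-area raised-cosine (Hanning) kernel of half width 50 ms by default,
giving a smooth instantaneous rate in Hz.  The dense rate is then reduced
to the ``n_bins`` (default 128) equal bins of the analysis window, the
vector the wavelet decomposition consumes.

Spikes outside the analysis window still contribute through their kernel
tails: the convolution is evaluated over an extended span and only then
restricted to the window, so window edges are handled by real data rather
than padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AnalysisWindow, SpikeTrain

DEFAULT_HALFWIDTH_MS = 50.0
DEFAULT_GRID_STEP_MS = 1.0


def hanning_kernel(halfwidth_ms: float, grid_step_ms: float) -> np.ndarray:
    """Discretized unit-area raised-cosine kernel.

    ``w(t) ∝ 0.5 (1 + cos(pi t / L))`` on ``[-L, L]`` with ``L`` the half
    width (half support), sampled at ``grid_step_ms`` and normalized so the
    discrete integral (sum x step, step in seconds) equals one.  The
    returned values are therefore in Hz per spike; the continuous-limit
    peak is ``1/L`` (20 Hz at L = 50 ms).
    """
    if not halfwidth_ms > 0:
        raise ValueError("halfwidth_ms must be positive")
    if not 0 < grid_step_ms <= halfwidth_ms:
        raise ValueError("grid_step_ms must be in (0, halfwidth_ms]")
    n_half = int(math.floor(halfwidth_ms / grid_step_ms + 1e-9))
    offsets = np.arange(-n_half, n_half + 1) * grid_step_ms
    w = 0.5 * (1.0 + np.cos(np.pi * offsets / halfwidth_ms))
    return w / (w.sum() * grid_step_ms / 1000.0)


@dataclass(frozen=True)
class RateFunction:
    """Dense and binned instantaneous rate of one trial over a window."""

    dense: np.ndarray          # Hz, at the dense grid midpoints
    binned: np.ndarray         # Hz, length window.n_bins
    window: AnalysisWindow
    kernel_halfwidth_ms: float
    grid_step_ms: float        # effective dense step (divides the bin width)

    @property
    def dense_times(self) -> np.ndarray:
        """Absolute times (s) of the dense samples (bin-midpoint grid)."""
        h = self.grid_step_ms / 1000.0
        return self.window.start + (np.arange(self.dense.size) + 0.5) * h


def _effective_step_ms(window: AnalysisWindow, grid_step_ms: float) -> tuple[float, int]:
    """Snap the requested step to the nearest exact divisor of the bin width."""
    bw = window.bin_width_ms
    m = max(1, int(round(bw / grid_step_ms)))
    return bw / m, m


def rate_function(train: SpikeTrain, window: AnalysisWindow,
                  halfwidth_ms: float = DEFAULT_HALFWIDTH_MS,
                  grid_step_ms: float = DEFAULT_GRID_STEP_MS) -> RateFunction:
    """Kernel-smoothed rate of one trial, dense and binned over ``window``.

    The requested ``grid_step_ms`` is snapped to the nearest exact divisor
    of the bin width (10.9375 / 11 ≈ 0.994 ms at defaults) so each bin
    averages an identical integer number of dense samples.  All spikes of
    the recording within kernel reach of the window contribute.  An empty
    train yields an all-zero rate.
    """
    h_ms, m = _effective_step_ms(window, grid_step_ms)
    h_s = h_ms / 1000.0
    L_s = halfwidth_ms / 1000.0
    n_total = window.n_bins * m
    n_half = int(np.floor(halfwidth_ms / h_ms + 1e-9))
    n_pad = 2 * n_half + 2  # full kernel support for any contributing spike

    # dense grid midpoints over the extended span; the kernel is evaluated
    # exactly at each spike's offsets and renormalized per spike so its
    # discrete mass is exactly one (no spike-time quantization)
    n_ext = n_total + 2 * n_pad
    grid0 = window.start + (0.5 - n_pad) * h_s
    dense_ext = np.zeros(n_ext)
    spikes = train.spike_times
    spikes = spikes[(spikes > window.start - L_s - h_s)
                    & (spikes < window.end + L_s + h_s)]
    if spikes.size:
        k_len = 2 * n_half + 3
        j0 = np.ceil((spikes - L_s - grid0) / h_s).astype(int)
        idx = j0[:, None] + np.arange(k_len)
        offsets = grid0 + idx * h_s - spikes[:, None]
        w = np.where(np.abs(offsets) <= L_s,
                     0.5 * (1.0 + np.cos(np.pi * offsets / L_s)), 0.0)
        w /= w.sum(axis=1, keepdims=True) * h_s
        # clamped indices only occur for spikes whose kernel cannot reach
        # the window; their mass piles into edge cells cropped below
        np.add.at(dense_ext, np.clip(idx, 0, n_ext - 1), w)
    dense = dense_ext[n_pad:n_pad + n_total]
    binned = dense.reshape(window.n_bins, m).mean(axis=1)
    return RateFunction(dense=dense, binned=binned, window=window,
                        kernel_halfwidth_ms=halfwidth_ms, grid_step_ms=h_ms)
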