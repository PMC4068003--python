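"""Detrended fluctuation analysis of population activity.

Order-1 DFA after Peng: mean-subtract the series, integrate, tile the
profile into non-overlapping windows of width ``w``, remove a per-window
linear trend, and measure the RMS residual ``F(w)``.  The scaling exponent
``beta`` is the least-squares slope of ``log2 F`` vs ``log2 w``:
``beta = 0.5`` for an uncorrelated series, ``~1`` for 1/f (pink) noise,
``~1.5`` for Brownian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import SpikeRaster

__all__ = ["DFAResult", "dfa_exponent", "population_signal", "DEFAULT_WINDOWS"]

# powers of two, 16 ms .. 2048 ms; below 16 ms the sampling resolution
# interferes and above ~2 s the scaling of neural population activity breaks
DEFAULT_WINDOWS = tuple(int(2 ** k) for k in range(4, 12))


@dataclass
class DFAResult:
    window_widths: np.ndarray
    fluctuation: np.ndarray
    beta: float


def population_signal(raster: SpikeRaster, step_ms: float = 1.0) -> np.ndarray:
    """Pooled spike counts per ``step_ms`` over the whole record."""
    n = int(round(raster.duration / step_ms))
    idx = (raster.times // step_ms).astype(np.int64)
    return np.bincount(idx[idx < n], minlength=n).astype(np.float64)


def dfa_exponent(signal: np.ndarray,
                 window_widths: Sequence[int] = DEFAULT_WINDOWS) -> DFAResult:
    """Order-1 DFA; returns F(w) and the fitted exponent beta.

    Windows are non-overlapping, forward-tiled; the trailing partial window
    is discarded.  Requires at least 4 full windows at the largest width.
    """
    x = np.asarray(signal, dtype=np.float64)
    widths = np.asarray(sorted(window_widths), dtype=np.int64)
    if x.size < 4 * widths.max():
        raise ValueError("signal must be at least 4x the largest window")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: DFA exponent undefined")
    profile = np.cumsum(x - x.mean())
    F = np.empty(widths.size)
    for i, w in enumerate(widths):
        n_win = profile.size // w
        seg = profile[:n_win * w].reshape(n_win, w)
        t = np.arange(w) - (w - 1) / 2.0
        slope = seg @ t / (t @ t)
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t
        F[i] = np.sqrt(np.mean(resid ** 2))
    if np.any(F <= 0):
        raise ValueError("zero fluctuation: DFA exponent undefined")
    beta = float(np.polyfit(np.log2(widths), np.log2(F), 1)[0])
    return DFAResult(window_widths=widths, fluctuation=F, beta=beta)
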