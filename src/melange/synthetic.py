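"""Synthetic inputs for every stage of the pipeline.

These generators exist so the full analysis path is exercisable and
testable without any recorded data:

* independent-Poisson rasters (the alpha = 0 reference, with closed-form
  avalanche statistics);
* an "in-vivo-like" raster whose avalanche sizes at one <IEI> bin follow a
  discretized lognormal — an explicit caricature (independent avalanches,
  geometric gaps) that mimics the statistical envelope of cortical
  recordings (tens of units, population rates of tens to hundreds of Hz),
  not their mechanism;
* fractional noise of known Hurst exponent (DFA calibration);
* multichannel LFP-like surrogates (oscillations + noise at 400 Hz).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .lfp import ContinuousTrace
from .raster import SpikeRaster

__all__ = ["make_poisson_raster", "make_invivo_like_raster",
           "make_fractional_noise", "make_lfp_surrogate"]


def make_poisson_raster(n_units: int, rate_hz: float, duration_ms: float,
                        seed: int) -> SpikeRaster:
    """Independent homogeneous Poisson units at ``rate_hz`` each."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_hz * duration_ms / 1000.0, size=n_units)
    units = np.repeat(np.arange(n_units), counts)
    times = rng.random(counts.sum()) * duration_ms
    raster = SpikeRaster(times=times, units=units, n_units=n_units,
                         duration=duration_ms,
                         meta={"kind": "poisson", "rate_hz": rate_hz,
                               "seed": seed, "empty": counts.sum() == 0})
    return raster


def make_invivo_like_raster(n_units: int = 100, target_rate_hz: float = 320.0,
                            duration_ms: float = 600_000.0, mu: float = 0.89,
                            sigma2: float = 1.2, seed: int = 0) -> SpikeRaster:
    """Raster whose avalanche sizes at ``bs = 1 <IEI>`` are lognormal.

    ``target_rate_hz`` is the pooled population rate R (the recordings this
    emulates span R ~ 37-1560 Hz); the bin grid is ``<IEI> = 1000/R`` ms.
    Avalanche sizes are drawn from the discretized lognormal(mu, sigma2);
    each avalanche of size s occupies ``d = ceil(s / spb)`` consecutive
    bins (so every bin is non-empty) and avalanches are separated by
    geometric numbers of empty bins whose mean is set by the constraint
    that the overall rate equals R.  Spike-to-unit assignment is uniform.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(sigma2))
    iei = 1000.0 / target_rate_hz
    n_bins_total = int(duration_ms / iei)
    # draw sizes: continuous lognormal rounded to the nearest integer,
    # conditioned on s >= 1 (matches the interval-mass discretization)
    mean_s = float(np.exp(mu + sigma2 / 2.0))
    n_guess = int(n_bins_total / mean_s * 1.3) + 100
    sizes = []
    while sum(len(b) for b in sizes) * mean_s < 1.3 * n_bins_total:
        draw = np.round(rng.lognormal(mu, sigma, n_guess)).astype(np.int64)
        sizes.append(draw[draw >= 1])
    sizes = np.concatenate(sizes)
    # occupied bins per avalanche: at most spb spikes per bin; the achieved
    # rate is E[s] per (E[d] + E[gap]) bins (one spike per bin-time = R), so
    # set the mean gap from the realized discretized sizes
    spb = 3
    d = np.ceil(sizes / spb).astype(np.int64)
    mean_gap = sizes.mean() - d.mean()
    if mean_gap < 1.0:
        raise ValueError("target rate unreachable: raise spikes-per-bin")
    p_gap = 1.0 / mean_gap
    gaps = rng.geometric(p_gap, size=sizes.size)  # >= 1 empty bin
    times = []
    bin_cursor = int(gaps[0])
    n_spikes = 0
    for s, dd, gap in zip(sizes, d, gaps):
        if bin_cursor + dd >= n_bins_total:
            break
        # distribute s spikes over dd bins, each bin >= 1 spike
        base = s // dd
        extra = s - base * dd
        per_bin = np.full(dd, base, dtype=np.int64)
        per_bin[:extra] += 1
        for j, m in enumerate(per_bin):
            lo = (bin_cursor + j) * iei
            times.append(lo + rng.random(m) * iei)
        n_spikes += s
        bin_cursor += int(dd + gap)
    times = np.sort(np.concatenate(times))
    units = rng.integers(0, n_units, size=times.size)
    return SpikeRaster(times=times, units=units, n_units=n_units,
                       duration=duration_ms,
                       meta={"kind": "invivo_like", "mu": mu,
                             "sigma2": sigma2, "target_R_hz": target_rate_hz,
                             "iei_ms": iei, "seed": seed})


def make_fractional_noise(hurst: float, length: int, seed: int) -> np.ndarray:
    """Gaussian noise with power spectrum ``S(f) ~ f^-(2H-1)``.

    Spectral synthesis: white Gaussian Fourier coefficients shaped by the
    target spectrum.  Order-1 DFA of such a series scales with exponent
    ``beta = H`` (H = 0.5 white, H = 1 pink).
    """
    if not 0.0 < hurst < 1.5:
        raise ValueError("hurst must lie in (0, 1.5)")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(length, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-(2.0 * hurst - 1.0) / 2.0)
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phases, n=length)
    return (x - x.mean()) / x.std()


def make_lfp_surrogate(n_channels: int = 50, duration_s: float = 300.0,
                       fs: float = 400.0,
                       oscillations_hz: Sequence[float] = (1.0, 3.0, 7.0),
                       oscillation_amp: float = 1.0,
                       noise_level: float = 0.5,
                       seed: int = 0) -> ContinuousTrace:
    """Multichannel LFP-like trace: low-frequency oscillations plus noise.

    Each channel is a sum of sinusoids at ``oscillations_hz`` with random
    phases and channel-specific amplitude jitter, plus white Gaussian noise
    of standard deviation ``noise_level``.  With both amplitudes zero the
    trace is identically zero (and yields no events).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    out = np.zeros((n_channels, n))
    for ch in range(n_channels):
        for f in oscillations_hz:
            a = oscillation_amp * (0.75 + 0.5 * rng.random())
            out[ch] += a * np.sin(2 * np.pi * f * t + 2 * np.pi * rng.random())
        if noise_level > 0:
            out[ch] += noise_level * rng.standard_normal(n)
    return ContinuousTrace(samples=out, fs=fs)
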