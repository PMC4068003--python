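"""Bin-size-dependent avalanche statistics.

Without a separation of time scales, avalanches cannot be delimited by
pauses; the standard workaround is temporal binning: pool all units, count
spikes in half-open bins of width ``bs``, and call each maximal run of
non-empty bins one avalanche.  Everything here is a function of the bin
size, which is the point — how the statistics move with ``bs``
discriminates dynamical regimes:

* ``<s>``: mean avalanche size as a function of ``bs``;
* ``f(s=1, bs)``: frequency of single-spike avalanches vs ``bs``,
  normalized to 1 at one mean inter-event interval — power law for driven
  critical dynamics, exponential for Poisson, robust to subsampling;
* ``sigma*``: bin-wise branching-ratio estimator, the mean of
  ``n_i / n_{i-1}`` over bins with a non-empty predecessor.

Bin sizes can be given in ms or in units of the mean inter-event interval
``<IEI> = 1/R`` of the pooled population, which removes the trivial
dependence on the population rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "BinnedCounts", "AvalancheSet", "SizeDistribution", "BranchingEstimate",
    "bin_spikes", "extract_avalanches", "mean_size", "f1_curve",
    "estimate_sigma", "sigma_curve", "mean_iei", "log_bin",
    "size_distribution",
]


@dataclass
class BinnedCounts:
    """Pooled spike counts in half-open bins ``[j*bs, (j+1)*bs)``."""

    counts: np.ndarray
    bin_size: float          # ms
    iei_units: Optional[float] = None  # bin size in <IEI>, if so specified

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass
class AvalancheSet:
    """Avalanche sizes extracted at one bin size."""

    sizes: np.ndarray
    bin_size: float           # ms
    iei: float                # <IEI> = 1/R of the source raster, ms
    boundary: np.ndarray = None  # True where the run touches the record edge

    def __post_init__(self):
        if self.boundary is None:
            self.boundary = np.zeros(self.sizes.shape, dtype=bool)

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)

    def interior(self) -> np.ndarray:
        """Sizes of avalanches that do not touch the record boundary."""
        return self.sizes[~self.boundary]


@dataclass
class SizeDistribution:
    """Avalanche-size frequencies, raw or logarithmically binned.

    For raw distributions ``support`` holds the observed integer sizes and
    ``frequency`` their absolute counts.  After :func:`log_bin`,
    ``frequency`` holds per-unit-size densities (count / bin width) at the
    geometric centre of each occupied bin.
    """

    support: np.ndarray
    frequency: np.ndarray
    log_binned: bool = False
    bin_edges: Optional[np.ndarray] = None
    note: str = ""

    @property
    def probability(self) -> np.ndarray:
        return self.frequency / self.frequency.sum()


@dataclass
class BranchingEstimate:
    """Bin-ratio branching-parameter estimate at one bin size."""

    sigma: float
    n_defined: int
    bin_size: float
    ratios: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------

def bin_spikes(raster: SpikeRaster, bs: float,
               time_resolution: float = 1e-3) -> BinnedCounts:
    """Pooled spike counts at bin size ``bs`` ms; trailing partial bin dropped."""
    if raster.n_spikes == 0:
        raise ValueError("cannot bin an empty raster")
    if bs < time_resolution:
        raise ValueError(f"bin size {bs} ms below time resolution")
    n_bins = int(raster.duration // bs)
    if n_bins < 1:
        raise ValueError("bin size exceeds record duration")
    idx = (raster.times // bs).astype(np.int64)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    return BinnedCounts(counts=counts, bin_size=float(bs))


def extract_avalanches(counts: BinnedCounts, iei: float = np.nan) -> AvalancheSet:
    """Maximal runs of non-empty bins -> avalanche sizes.

    Runs touching the start or end of the record are kept but flagged as
    boundary avalanches, since their true extent is unknown.
    """
    c = counts.counts
    occ = np.concatenate([[False], c > 0, [False]])
    d = np.diff(occ.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    csum = np.concatenate([[0], np.cumsum(c)])
    sizes = csum[ends] - csum[starts]
    boundary = (starts == 0) | (ends == c.size)
    return AvalancheSet(sizes=sizes, bin_size=counts.bin_size, iei=iei,
                        boundary=boundary)


def mean_size(av: AvalancheSet) -> float:
    """Arithmetic mean avalanche size ``<s>``."""
    if av.n_avalanches == 0:
        raise ValueError("no avalanches")
    return float(av.sizes.mean())


def mean_iei(raster: SpikeRaster) -> float:
    """Mean inter-event interval of the pooled population, ms (= 1/R)."""
    if raster.n_spikes == 0:
        raise ValueError("empty raster has no <IEI>")
    return raster.duration / raster.n_spikes


def avalanches_at(raster: SpikeRaster, bs_ms: float) -> AvalancheSet:
    """Bin at ``bs_ms`` and extract avalanches, carrying the raster's <IEI>."""
    return extract_avalanches(bin_spikes(raster, bs_ms), iei=mean_iei(raster))


def size_distribution(av: AvalancheSet, drop_boundary: bool = False) -> SizeDistribution:
    sizes = av.interior() if drop_boundary else av.sizes
    support, freq = np.unique(sizes, return_counts=True)
    return SizeDistribution(support=support.astype(float),
                            frequency=freq.astype(float))


def f1_curve(raster: SpikeRaster, bin_sizes_iei: Sequence[float]) -> dict:
    """Normalized frequency of size-1 avalanches vs bin size in <IEI> units.

    Returns ``{bs_iei: f(s=1, bs) / f(s=1, bs=1 <IEI>)}``.  The grid must
    contain the normalization point ``bs = 1 <IEI>``.
    """
    bs_list = list(bin_sizes_iei)
    if not any(np.isclose(b, 1.0) for b in bs_list):
        raise ValueError("bin-size grid must include 1 <IEI> for normalization")
    iei = mean_iei(raster)
    raw = {}
    for mult in bs_list:
        av = avalanches_at(raster, mult * iei)
        raw[mult] = float((av.sizes == 1).sum())
    norm = next(raw[m] for m in raw if np.isclose(m, 1.0))
    if norm == 0:
        raise ValueError("no size-1 avalanches at the normalization bin size")
    return {m: v / norm for m, v in raw.items()}


def estimate_sigma(counts: BinnedCounts, keep_ratios: bool = False) -> BranchingEstimate:
    """Bin-ratio branching parameter sigma* at one bin size.

    ``sigma*_i = n_i / n_{i-1}`` is defined only where the predecessor bin
    is non-empty; an empty successor counts as a ratio of 0.
    """
    c = counts.counts.astype(float)
    prev, nxt = c[:-1], c[1:]
    defined = prev > 0
    if not defined.any():
        raise ValueError("no defined ratios: every predecessor bin is empty")
    ratios = nxt[defined] / prev[defined]
    return BranchingEstimate(sigma=float(ratios.mean()),
                             n_defined=int(defined.sum()),
                             bin_size=counts.bin_size,
                             ratios=ratios if keep_ratios else None)


def sigma_curve(raster: SpikeRaster, bin_sizes_ms: Sequence[float]) -> "np.ndarray":
    """sigma* over a bin-size grid; returns array of (bs_ms, sigma*)."""
    out = np.empty((len(bin_sizes_ms), 2))
    for i, bs in enumerate(bin_sizes_ms):
        out[i, 0] = bs
        out[i, 1] = estimate_sigma(bin_spikes(raster, bs)).sigma
    return out


def log_bin(dist: SizeDistribution, bins_per_decade: int = 10) -> SizeDistribution:
    """Logarithmic re-binning of a raw size distribution.

    Geometric bin edges; the height of an occupied bin is its total count
    divided by the bin width (a per-unit-size density), located at the
    geometric mean of the edges.  An exact power law stays a power law
    under this transform.
    """
    if dist.log_binned:
        raise ValueError("distribution is already log-binned")
    if dist.support.size == 0:
        raise ValueError("empty distribution")
    lo = max(1.0, float(dist.support.min()))
    hi = float(dist.support.max())
    n_edges = max(2, int(np.ceil(np.log10((hi + 1) / lo) * bins_per_decade)) + 1)
    # integer-aligned edges: sizes are integers, so fractional-width bins at
    # small s would distort the density; duplicates after rounding collapse
    edges = np.unique(np.round(np.geomspace(lo, hi + 1, n_edges)))
    which = np.searchsorted(edges, dist.support, side="right") - 1
    which = np.clip(which, 0, edges.size - 2)
    counts = np.bincount(which, weights=dist.frequency, minlength=edges.size - 1)
    widths = np.diff(edges)
    occupied = counts > 0
    centres = np.sqrt(edges[:-1] * np.maximum(edges[1:] - 1, edges[:-1]))
    return SizeDistribution(support=centres[occupied],
                            frequency=(counts / widths)[occupied],
                            log_binned=True, bin_edges=edges,
                            note=f"log-binned, {bins_per_decade}/decade")
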