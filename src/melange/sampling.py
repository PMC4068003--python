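"""Subsampling of spike rasters.

Experiments record on the order of a hundred units out of the whole
network; subsampling a model raster the same way is required before any
comparison with recorded activity.  Two schemes are provided: ``random``
(N units drawn uniformly without replacement) and ``grid`` (an m x m block
of lattice units at a fixed spacing, centred on the lattice), mirroring the
sampling geometries used to probe the spatial topology dependence of
``f(s=1, bs)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .raster import SpikeRaster

__all__ = ["SamplingScheme", "subsample", "grid_unit_ids"]


@dataclass
class SamplingScheme:
    """Which units to keep.

    ``kind='random'`` keeps ``N`` units drawn uniformly; ``kind='grid'``
    keeps a ``side x side`` block with ``spacing`` lattice units between
    sampled sites, centred on the lattice (requires a lattice-indexed
    raster).
    """

    kind: str = "random"
    N: int = 100
    side: int = 8
    spacing: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random", "grid"):
            raise ValueError("kind must be 'random' or 'grid'")


def grid_unit_ids(L: int, side: int, spacing: int) -> np.ndarray:
    """Unit ids of a centred ``side x side`` grid with the given spacing."""
    span = (side - 1) * spacing
    if span >= L:
        raise ValueError(f"grid span {span} does not fit on an L={L} lattice")
    start = (L - 1 - span) // 2
    coords = start + spacing * np.arange(side)
    rows, cols = np.meshgrid(coords, coords, indexing="ij")
    return (rows * L + cols).ravel()


def subsample(raster: SpikeRaster, scheme: SamplingScheme) -> SpikeRaster:
    """Restrict a raster to the units selected by ``scheme``.

    Spike times are untouched and the duration is unchanged; kept units are
    relabelled ``0..N-1`` preserving their original order.
    """
    if scheme.kind == "random":
        if scheme.N > raster.n_units:
            raise ValueError("cannot sample more units than the raster has")
        rng = np.random.default_rng(scheme.seed)
        selected = np.sort(rng.choice(raster.n_units, scheme.N, replace=False))
    else:
        if raster.unit_positions is None:
            raise ValueError("grid sampling requires a lattice-indexed raster")
        L = int(raster.unit_positions[:, 0].max()) + 1
        selected = np.sort(grid_unit_ids(L, scheme.side, scheme.spacing))
    relabel = np.full(raster.n_units, -1, dtype=np.int64)
    relabel[selected] = np.arange(selected.size)
    keep = relabel[raster.units] >= 0
    return SpikeRaster(
        times=raster.times[keep],
        units=relabel[raster.units[keep]],
        n_units=int(selected.size),
        duration=raster.duration,
        origin=None if raster.origin is None else raster.origin[keep],
        unit_positions=None if raster.unit_positions is None
        else raster.unit_positions[selected],
        meta={**raster.meta, "subsampled": scheme},
    )
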