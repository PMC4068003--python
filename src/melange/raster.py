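"""Spike raster container and plain-text / HDF5 round-trip I/O.

The :class:`SpikeRaster` is the common currency between the simulators,
the subsampling stage and all avalanche statistics.  Spike times are kept
in milliseconds in a single flat, time-sorted array with a parallel array
of unit labels; this layout makes population-level binning (the operation
everything downstream is built on) a single ``bincount``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

__all__ = ["SpikeRaster", "read_raster_text", "write_raster_text",
           "read_raster_h5", "write_raster_h5"]


@dataclass
class SpikeRaster:
    """Parallel spike times of ``n_units`` units over ``duration`` ms.

    Parameters
    ----------
    times
        Spike times in ms, sorted ascending, ``0 <= t < duration``.
    units
        Integer unit label per spike, in ``[0, n_units)``.
    n_units
        Number of recorded units (units may be silent).
    duration
        Record length in ms.
    origin
        Optional per-spike flag: 1 for externally driven ("input") spikes,
        0 for synaptically propagated ones.
    unit_positions
        Optional ``(n_units, 2)`` integer lattice coordinates, present for
        rasters produced by the lattice model (needed for grid subsampling).
    meta
        Free-form provenance (model config, seed, ...).
    """

    times: np.ndarray
    units: np.ndarray
    n_units: int
    duration: float
    origin: Optional[np.ndarray] = None
    unit_positions: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.times.shape != self.units.shape:
            raise ValueError("times and units must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.units = self.units[order]
            if self.origin is not None:
                self.origin = np.asarray(self.origin)[order]
        if self.times.size:
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if self.units.min() < 0 or self.units.max() >= self.n_units:
                raise ValueError("unit labels must lie in [0, n_units)")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=np.uint8)
            if self.origin.shape != self.times.shape:
                raise ValueError("origin must be parallel to times")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def population_rate(self) -> float:
        """Pooled rate R of all units together, in Hz."""
        return self.n_spikes / self.duration * 1000.0

    @property
    def unit_rate(self) -> float:
        """Mean single-unit rate r = R / n_units, in Hz."""
        return self.population_rate / self.n_units

    def spike_times_of(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]


# ---------------------------------------------------------------------------
# plain-text I/O: two columns, unit id and spike time in ms
# ---------------------------------------------------------------------------

def write_raster_text(raster: SpikeRaster, path) -> None:
    header = json.dumps({"n_units": raster.n_units,
                         "duration_ms": raster.duration})
    data = np.column_stack([raster.units.astype(float), raster.times])
    np.savetxt(path, data, fmt=["%d", "%.6f"], header=header)


def read_raster_text(path) -> SpikeRaster:
    with open(path) as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip())
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        units = np.empty(0, dtype=np.int64)
        times = np.empty(0, dtype=np.float64)
    else:
        units = data[:, 0].astype(np.int64)
        times = data[:, 1]
    return SpikeRaster(times=times, units=units,
                       n_units=int(meta["n_units"]),
                       duration=float(meta["duration_ms"]))


# ---------------------------------------------------------------------------
# HDF5 I/O with full metadata
# ---------------------------------------------------------------------------

def write_raster_h5(raster: SpikeRaster, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=raster.times)
        fh.create_dataset("units", data=raster.units)
        if raster.origin is not None:
            fh.create_dataset("origin", data=raster.origin)
        if raster.unit_positions is not None:
            fh.create_dataset("unit_positions", data=raster.unit_positions)
        fh.attrs["n_units"] = raster.n_units
        fh.attrs["duration_ms"] = raster.duration
        fh.attrs["meta"] = json.dumps(raster.meta, default=str)


def read_raster_h5(path) -> SpikeRaster:
    with h5py.File(path, "r") as fh:
        kwargs = dict(
            times=fh["times"][...],
            units=fh["units"][...],
            n_units=int(fh.attrs["n_units"]),
            duration=float(fh.attrs["duration_ms"]),
            meta=json.loads(fh.attrs["meta"]),
        )
        if "origin" in fh:
            kwargs["origin"] = fh["origin"][...]
        if "unit_positions" in fh:
            kwargs["unit_positions"] = fh["unit_positions"][...]
    return SpikeRaster(**kwargs)
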