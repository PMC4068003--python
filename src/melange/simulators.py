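"""Critical spiking-network simulators.

Two models are implemented, both with 1 ms synchronous update steps:

* a lattice of non-leaky integrate-and-fire neurons (``L x L`` grid, nearest
  neighbour coupling ``alpha``, open boundaries).  A neuron with membrane
  potential ``V > theta`` spikes; its potential drops by 4 and each existing
  neighbour gains ``alpha``.  At ``alpha = 1`` and vanishing drive this is the
  classic Bak-Tang-Wiesenfeld sandpile and self-organizes to a critical
  state; ``alpha < 1`` introduces bulk dissipation and makes it sub-critical.
* a stochastic branching network: an active neuron activates each of ``k``
  uniformly re-drawn postsynaptic targets with probability
  ``p = alpha / k``; a target is additionally lost with probability
  ``p_diss`` ("projects outside the grid").  The process is critical at
  ``alpha = 1`` (infinite-size limit).

Both models run in one of two regimes:

* **STS** (separation of time scales): external input is applied only when
  the network is quiescent, one unit at a time, and the triggered cascade is
  one avalanche (:func:`run_sts`).
* **driven**: every unit independently receives Poisson input at rate ``h``
  that sets it above threshold, concurrently with propagation; avalanches
  overlap into a melange (:func:`run_driven`).

The hot loops are compiled with numba; the single-step operations
(:func:`soc_step`, :func:`branching_step`) are plain numpy and serve as the
inspectable reference semantics that the compiled kernels are tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .raster import SpikeRaster

__all__ = [
    "SOCConfig", "BranchingConfig", "SOCState", "AvalancheRecord",
    "CascadeSample", "soc_step", "branching_step", "run_sts",
    "run_sts_raster", "run_driven", "stationary_rate", "calibrate_drive",
    "lattice_positions",
]

_EPS = 1e-6  # amount by which drive lifts a unit above threshold


# ---------------------------------------------------------------------------
# configurations and state
# ---------------------------------------------------------------------------

@dataclass
class SOCConfig:
    """Parameters of the lattice model.

    ``drive_rate`` is the per-neuron Poisson input rate h in Hz; it is only
    meaningful in ``driven`` mode (STS mode applies input event-by-event).
    """

    L: int = 50
    alpha: float = 1.0
    drive_rate: float = 0.0
    theta: float = 0.0
    mode: str = "STS"
    step_ms: float = 1.0
    seed: int = 0
    transient_steps: int = 100_000
    transient_avalanches: int = 10_000
    size_cap: int = 10_000_000
    rate_ceiling: float = 500.0  # Hz per unit; runaway guard in driven mode

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.drive_rate < 0:
            raise ValueError("drive_rate must be >= 0")
        if self.mode not in ("STS", "driven"):
            raise ValueError("mode must be 'STS' or 'driven'")

    @property
    def n_neurons(self) -> int:
        return self.L * self.L


@dataclass
class BranchingConfig:
    """Parameters of the stochastic branching model."""

    n_neurons: int = 2500
    k: int = 4
    alpha: float = 1.0
    p_diss: float = 0.001
    drive_rate: float = 0.0
    mode: str = "STS"
    step_ms: float = 1.0
    seed: int = 0
    transient_steps: int = 100_000
    transient_avalanches: int = 0
    size_cap: int = 10_000_000
    rate_ceiling: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha / self.k <= 1.0:
            raise ValueError("activation probability p = alpha/k not in [0, 1]")
        if not 0.0 <= self.p_diss <= 1.0:
            raise ValueError("p_diss must lie in [0, 1]")
        if self.mode not in ("STS", "driven"):
            raise ValueError("mode must be 'STS' or 'driven'")

    @property
    def p_activation(self) -> float:
        """Per-target activation probability p * (1 - p_diss)."""
        return self.alpha / self.k * (1.0 - self.p_diss)


@dataclass
class SOCState:
    """Evolving lattice-model state: membrane potentials and time."""

    V: np.ndarray
    t: float = 0.0


@dataclass
class AvalancheRecord:
    size: int
    duration: int
    trigger_time: float
    capped: bool = False


@dataclass
class CascadeSample:
    """Avalanches from an STS run, as parallel arrays.

    ``trigger_times`` are cumulative active steps (quiescent waiting time is
    notional under STS and carries no information).  Indexing yields
    :class:`AvalancheRecord` objects.
    """

    sizes: np.ndarray
    durations: np.ndarray
    trigger_times: np.ndarray
    capped: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.sizes.size)

    def __getitem__(self, i: int) -> AvalancheRecord:
        return AvalancheRecord(int(self.sizes[i]), int(self.durations[i]),
                               float(self.trigger_times[i]), bool(self.capped[i]))

    @property
    def any_capped(self) -> bool:
        return bool(self.capped.any())


def lattice_positions(L: int) -> np.ndarray:
    """(row, col) coordinates of unit ``i = row * L + col``."""
    rows, cols = np.divmod(np.arange(L * L), L)
    return np.column_stack([rows, cols]).astype(np.int64)


def _init_potentials(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    # uniform on [theta - 4, theta): quiescent, pre-transient start
    return theta - 4.0 + 4.0 * rng.random(n)


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """Child seeds (< 2**32) for the numba kernels."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


# ---------------------------------------------------------------------------
# reference single-step semantics (numpy, used by tests and small runs)
# ---------------------------------------------------------------------------

def soc_step(state: SOCState, cfg: SOCConfig,
             forced_units: Iterable[int] = ()) -> Tuple[SOCState, np.ndarray]:
    """One synchronous lattice update; returns new state and spiker ids.

    ``forced_units`` are set just above threshold before the threshold test
    (units already above threshold are left unchanged).  Every unit with
    ``V > theta`` spikes: its potential drops by 4, each existing lattice
    neighbour gains ``alpha``; at the open boundary the remaining charge is
    lost.  Time advances by one step.
    """
    L = cfg.L
    V = state.V.copy()
    forced = np.asarray(list(forced_units), dtype=np.int64)
    if forced.size:
        below = V[forced] <= cfg.theta
        V[forced[below]] = cfg.theta + _EPS
    spikers = np.flatnonzero(V > cfg.theta)
    if spikers.size:
        grid = np.zeros((L, L))
        spk = np.zeros((L, L), dtype=bool)
        spk.flat[spikers] = True
        grid[spk] -= 4.0
        a = cfg.alpha
        grid[:-1, :][spk[1:, :]] += a   # deliver up
        grid[1:, :][spk[:-1, :]] += a   # deliver down
        grid[:, :-1][spk[:, 1:]] += a   # deliver left
        grid[:, 1:][spk[:, :-1]] += a   # deliver right
        V += grid.ravel()
    return SOCState(V=V, t=state.t + cfg.step_ms), spikers


def branching_step(active_set: Sequence[int], cfg: BranchingConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One step of the branching model; returns the next active set.

    Each active unit draws ``k`` targets uniformly with replacement; each
    target independently becomes active with probability
    ``alpha/k * (1 - p_diss)``.  A unit activated by several sources is
    active exactly once.
    """
    active = np.asarray(list(active_set), dtype=np.int64)
    if active.size == 0:
        return np.empty(0, dtype=np.int64)
    targets = rng.integers(0, cfg.n_neurons, size=(active.size, cfg.k))
    hits = rng.random((active.size, cfg.k)) < cfg.p_activation
    return np.unique(targets[hits])


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _soc_sts_kernel(V, L, alpha, theta, n_avalanches, size_cap, seed,
                    record, gap_steps, record_from):
    np.random.seed(seed)
    n = L * L
    delta = np.zeros(n, np.float64)
    touched = np.empty(n, np.int64)
    in_touched = np.zeros(n, np.uint8)
    active = np.empty(n, np.int64)
    sizes = np.empty(n_avalanches, np.int64)
    durations = np.empty(n_avalanches, np.int64)
    capped = np.zeros(n_avalanches, np.uint8)
    cap = 65536
    rec_t = np.empty(cap, np.int64)
    rec_u = np.empty(cap, np.int32)
    nsp = 0
    t_now = 0
    for a in range(n_avalanches):
        u0 = np.random.randint(0, n)
        if V[u0] <= theta:
            V[u0] = theta + 1e-6
        active[0] = u0
        n_act = 1
        size = 0
        dur = 0
        while n_act > 0:
            size += n_act
            dur += 1
            if record == 1 and a >= record_from:
                if nsp + n_act > cap:
                    newcap = cap * 2
                    while newcap < nsp + n_act:
                        newcap *= 2
                    tmp_t = np.empty(newcap, np.int64)
                    tmp_t[:nsp] = rec_t[:nsp]
                    rec_t = tmp_t
                    tmp_u = np.empty(newcap, np.int32)
                    tmp_u[:nsp] = rec_u[:nsp]
                    rec_u = tmp_u
                    cap = newcap
                for idx in range(n_act):
                    rec_t[nsp] = t_now
                    rec_u[nsp] = active[idx]
                    nsp += 1
            t_now += 1
            if size > size_cap:
                capped[a] = 1
                for idx in range(n_act):
                    V[active[idx]] = theta - 2.0
                n_act = 0
                break
            n_t = 0
            for idx in range(n_act):
                u = active[idx]
                delta[u] -= 4.0
                if in_touched[u] == 0:
                    in_touched[u] = 1
                    touched[n_t] = u
                    n_t += 1
                r = u // L
                c = u - r * L
                if r > 0:
                    v = u - L
                    delta[v] += alpha
                    if in_touched[v] == 0:
                        in_touched[v] = 1
                        touched[n_t] = v
                        n_t += 1
                if r < L - 1:
                    v = u + L
                    delta[v] += alpha
                    if in_touched[v] == 0:
                        in_touched[v] = 1
                        touched[n_t] = v
                        n_t += 1
                if c > 0:
                    v = u - 1
                    delta[v] += alpha
                    if in_touched[v] == 0:
                        in_touched[v] = 1
                        touched[n_t] = v
                        n_t += 1
                if c < L - 1:
                    v = u + 1
                    delta[v] += alpha
                    if in_touched[v] == 0:
                        in_touched[v] = 1
                        touched[n_t] = v
                        n_t += 1
            n_act = 0
            for j in range(n_t):
                u = touched[j]
                V[u] += delta[u]
                delta[u] = 0.0
                in_touched[u] = 0
                if V[u] > theta:
                    active[n_act] = u
                    n_act += 1
        sizes[a] = size
        durations[a] = dur
        t_now += gap_steps
    return sizes, durations, capped, rec_t[:nsp], rec_u[:nsp]


@njit(cache=True)
def _soc_driven_kernel(V, L, alpha, theta, p_drive, n_steps,
                       max_spikes_per_ms, seed, record, count_from):
    np.random.seed(seed)
    n = L * L
    nkeep = 0
    delta = np.zeros(n, np.float64)
    touched = np.empty(n, np.int64)
    in_touched = np.zeros(n, np.uint8)
    active = np.empty(n, np.int64)
    is_above = np.zeros(n, np.uint8)
    input_flag = np.zeros(n, np.uint8)
    cap = 65536
    times = np.empty(cap, np.int64)
    out_units = np.empty(cap, np.int32)
    origin = np.empty(cap, np.uint8)
    nsp = 0
    n_act = 0
    aborted = -1
    block = 0
    for t in range(n_steps):
        if p_drive > 0.0:
            nd = np.random.binomial(n, p_drive)
            for _ in range(nd):
                u = np.random.randint(0, n)
                if is_above[u] == 0:
                    V[u] = theta + 1e-6
                    is_above[u] = 1
                    input_flag[u] = 1
                    active[n_act] = u
                    n_act += 1
        if n_act == 0:
            continue
        block += n_act
        if t % 1024 == 1023:
            if block > max_spikes_per_ms * 1024:
                aborted = t
                break
            block = 0
        if record == 1 and nsp + n_act > cap:
            newcap = cap * 2
            while newcap < nsp + n_act:
                newcap *= 2
            tmp_t = np.empty(newcap, np.int64)
            tmp_t[:nsp] = times[:nsp]
            times = tmp_t
            tmp_u = np.empty(newcap, np.int32)
            tmp_u[:nsp] = out_units[:nsp]
            out_units = tmp_u
            tmp_o = np.empty(newcap, np.uint8)
            tmp_o[:nsp] = origin[:nsp]
            origin = tmp_o
            cap = newcap
        n_t = 0
        for idx in range(n_act):
            u = active[idx]
            if record == 1:
                times[nsp] = t
                out_units[nsp] = u
                origin[nsp] = input_flag[u]
                nsp += 1
            if t >= count_from:
                nkeep += 1
            input_flag[u] = 0
            delta[u] -= 4.0
            if in_touched[u] == 0:
                in_touched[u] = 1
                touched[n_t] = u
                n_t += 1
            r = u // L
            c = u - r * L
            if r > 0:
                v = u - L
                delta[v] += alpha
                if in_touched[v] == 0:
                    in_touched[v] = 1
                    touched[n_t] = v
                    n_t += 1
            if r < L - 1:
                v = u + L
                delta[v] += alpha
                if in_touched[v] == 0:
                    in_touched[v] = 1
                    touched[n_t] = v
                    n_t += 1
            if c > 0:
                v = u - 1
                delta[v] += alpha
                if in_touched[v] == 0:
                    in_touched[v] = 1
                    touched[n_t] = v
                    n_t += 1
            if c < L - 1:
                v = u + 1
                delta[v] += alpha
                if in_touched[v] == 0:
                    in_touched[v] = 1
                    touched[n_t] = v
                    n_t += 1
        n_act = 0
        for j in range(n_t):
            u = touched[j]
            V[u] += delta[u]
            delta[u] = 0.0
            in_touched[u] = 0
            if V[u] > theta:
                active[n_act] = u
                n_act += 1
                is_above[u] = 1
            else:
                is_above[u] = 0
    return times[:nsp], out_units[:nsp], origin[:nsp], nkeep, aborted


@njit(cache=True)
def _branching_sts_kernel(n, k, p_act, n_avalanches, size_cap, seed,
                          record, gap_steps, record_from):
    np.random.seed(seed)
    cur = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    marked = np.zeros(n, np.uint8)
    sizes = np.empty(n_avalanches, np.int64)
    durations = np.empty(n_avalanches, np.int64)
    capped = np.zeros(n_avalanches, np.uint8)
    cap = 65536
    rec_t = np.empty(cap, np.int64)
    rec_u = np.empty(cap, np.int32)
    nsp = 0
    t_now = 0
    for a in range(n_avalanches):
        cur[0] = np.random.randint(0, n)
        n_cur = 1
        size = 0
        dur = 0
        while n_cur > 0:
            size += n_cur
            dur += 1
            if record == 1 and a >= record_from:
                if nsp + n_cur > cap:
                    newcap = cap * 2
                    while newcap < nsp + n_cur:
                        newcap *= 2
                    tmp_t = np.empty(newcap, np.int64)
                    tmp_t[:nsp] = rec_t[:nsp]
                    rec_t = tmp_t
                    tmp_u = np.empty(newcap, np.int32)
                    tmp_u[:nsp] = rec_u[:nsp]
                    rec_u = tmp_u
                    cap = newcap
                for i in range(n_cur):
                    rec_t[nsp] = t_now
                    rec_u[nsp] = cur[i]
                    nsp += 1
            t_now += 1
            if size > size_cap:
                capped[a] = 1
                break
            n_nxt = 0
            for i in range(n_cur):
                for _ in range(k):
                    if np.random.random() < p_act:
                        v = np.random.randint(0, n)
                        if marked[v] == 0:
                            marked[v] = 1
                            nxt[n_nxt] = v
                            n_nxt += 1
            for j in range(n_nxt):
                marked[nxt[j]] = 0
            tmp = cur
            cur = nxt
            nxt = tmp
            n_cur = n_nxt
        sizes[a] = size
        durations[a] = dur
        t_now += gap_steps
    return sizes, durations, capped, rec_t[:nsp], rec_u[:nsp]


@njit(cache=True)
def _branching_driven_kernel(n, k, p_act, p_drive, n_steps,
                             max_spikes_per_ms, seed, record, count_from):
    np.random.seed(seed)
    nkeep = 0
    cur = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    in_cur = np.zeros(n, np.uint8)
    in_nxt = np.zeros(n, np.uint8)
    is_input = np.zeros(n, np.uint8)
    cap = 65536
    times = np.empty(cap, np.int64)
    out_units = np.empty(cap, np.int32)
    origin = np.empty(cap, np.uint8)
    nsp = 0
    n_cur = 0
    aborted = -1
    block = 0
    for t in range(n_steps):
        if p_drive > 0.0:
            nd = np.random.binomial(n, p_drive)
            for _ in range(nd):
                u = np.random.randint(0, n)
                if in_cur[u] == 0:
                    in_cur[u] = 1
                    is_input[u] = 1
                    cur[n_cur] = u
                    n_cur += 1
        if n_cur == 0:
            continue
        block += n_cur
        if t % 1024 == 1023:
            if block > max_spikes_per_ms * 1024:
                aborted = t
                break
            block = 0
        if record == 1 and nsp + n_cur > cap:
            newcap = cap * 2
            while newcap < nsp + n_cur:
                newcap *= 2
            tmp_t = np.empty(newcap, np.int64)
            tmp_t[:nsp] = times[:nsp]
            times = tmp_t
            tmp_u = np.empty(newcap, np.int32)
            tmp_u[:nsp] = out_units[:nsp]
            out_units = tmp_u
            tmp_o = np.empty(newcap, np.uint8)
            tmp_o[:nsp] = origin[:nsp]
            origin = tmp_o
            cap = newcap
        n_nxt = 0
        for i in range(n_cur):
            u = cur[i]
            if record == 1:
                times[nsp] = t
                out_units[nsp] = u
                origin[nsp] = is_input[u]
                nsp += 1
            if t >= count_from:
                nkeep += 1
            is_input[u] = 0
            for _ in range(k):
                if np.random.random() < p_act:
                    v = np.random.randint(0, n)
                    if in_nxt[v] == 0:
                        in_nxt[v] = 1
                        nxt[n_nxt] = v
                        n_nxt += 1
        for i in range(n_cur):
            in_cur[cur[i]] = 0
        for j in range(n_nxt):
            in_nxt[nxt[j]] = 0
            in_cur[nxt[j]] = 1
        tmp = cur
        cur = nxt
        nxt = tmp
        n_cur = n_nxt
    return times[:nsp], out_units[:nsp], origin[:nsp], nkeep, aborted


# ---------------------------------------------------------------------------
# run-level API
# ---------------------------------------------------------------------------

Config = Union[SOCConfig, BranchingConfig]


def run_sts(cfg: Config, n_avalanches: int,
            seed: Optional[int] = None) -> CascadeSample:
    """Collect ``n_avalanches`` avalanches in separation-of-time-scales mode.

    When the network is quiescent one uniformly random unit is set above
    threshold and the triggered cascade is run to extinction; its total spike
    count is one avalanche.  ``transient_avalanches`` initial avalanches are
    run and discarded first (they relax the lattice into its stationary
    state; the branching model is memoryless between cascades).  Cascades
    hitting ``size_cap`` are aborted and flagged.
    """
    if cfg.mode != "STS":
        raise ValueError("run_sts requires mode='STS'")
    if n_avalanches < 1:
        raise ValueError("n_avalanches must be >= 1")
    seed = cfg.seed if seed is None else seed
    kernel_seed = int(_derive_seeds(seed, 1)[0])
    n_trans = cfg.transient_avalanches
    total = n_trans + n_avalanches
    if isinstance(cfg, SOCConfig):
        rng = np.random.default_rng(_derive_seeds(seed, 2)[1])
        V = _init_potentials(cfg.n_neurons, cfg.theta, rng)
        sizes, durations, capped, _, _ = _soc_sts_kernel(
            V, cfg.L, cfg.alpha, cfg.theta, total, cfg.size_cap, kernel_seed,
            0, 0, total)
    else:
        sizes, durations, capped, _, _ = _branching_sts_kernel(
            cfg.n_neurons, cfg.k, cfg.p_activation, total, cfg.size_cap,
            kernel_seed, 0, 0, total)
    sizes = sizes[n_trans:]
    durations = durations[n_trans:]
    capped = capped[n_trans:]
    trig = np.concatenate([[0], np.cumsum(durations)[:-1]]).astype(float)
    return CascadeSample(sizes=sizes, durations=durations, trigger_times=trig,
                         capped=capped.astype(bool),
                         meta={"cfg": cfg, "seed": seed})


def run_sts_raster(cfg: Config, n_avalanches: int, gap_ms: float = 10_000.0,
                   seed: Optional[int] = None) -> SpikeRaster:
    """STS run rendered as a spike raster with explicit quiescent gaps.

    Under a separation of time scales the pauses between avalanches are
    arbitrarily long; for binned statistics they must merely be much longer
    than any bin size and any avalanche, so a fixed ``gap_ms`` is inserted
    between consecutive cascades (default 10 s, versus <= ~1 s cascades and
    <= 0.5 s bins).  Spike times within cascades advance 1 step per
    synchronous update.
    """
    if cfg.mode != "STS":
        raise ValueError("run_sts_raster requires mode='STS'")
    seed = cfg.seed if seed is None else seed
    kernel_seed = int(_derive_seeds(seed, 1)[0])
    n_trans = cfg.transient_avalanches
    total = n_trans + n_avalanches
    gap_steps = int(round(gap_ms / cfg.step_ms))
    if isinstance(cfg, SOCConfig):
        rng = np.random.default_rng(_derive_seeds(seed, 2)[1])
        V = _init_potentials(cfg.n_neurons, cfg.theta, rng)
        sizes, durations, capped, times, units = _soc_sts_kernel(
            V, cfg.L, cfg.alpha, cfg.theta, total, cfg.size_cap, kernel_seed,
            1, gap_steps, n_trans)
        positions = lattice_positions(cfg.L)
    else:
        sizes, durations, capped, times, units = _branching_sts_kernel(
            cfg.n_neurons, cfg.k, cfg.p_activation, total, cfg.size_cap,
            kernel_seed, 1, gap_steps, n_trans)
        positions = None
    t0 = times[0] if times.size else 0
    duration = (times[-1] - t0 + gap_steps) * cfg.step_ms if times.size else gap_ms
    return SpikeRaster(times=(times - t0) * cfg.step_ms,
                       units=units.astype(np.int64),
                       n_units=cfg.n_neurons, duration=float(duration),
                       unit_positions=positions,
                       meta={"cfg": cfg, "seed": seed, "gap_ms": gap_ms,
                             "sts": True})


def run_driven(cfg: Config, duration_ms: float,
               seed: Optional[int] = None) -> SpikeRaster:
    """Simulate the driven (``h > 0``) regime and return the spike raster.

    Each unit independently receives Poisson input at rate ``drive_rate``
    (per step probability ``h * step_ms / 1000``) that sets it above
    threshold, concurrently with avalanche propagation.  ``transient_steps``
    are simulated and discarded before the returned record starts at t = 0.
    Per-spike ``origin`` flags distinguish input spikes (drive landed on a
    sub-threshold unit) from propagated spikes.  Sustained population rates
    above ``rate_ceiling`` per unit abort with a diagnostic.
    """
    if cfg.mode != "driven":
        raise ValueError("run_driven requires mode='driven'")
    if cfg.drive_rate <= 0:
        raise ValueError("driven mode requires drive_rate > 0")
    seed = cfg.seed if seed is None else seed
    seeds = _derive_seeds(seed, 2)
    n_steps = int(round(cfg.transient_steps + duration_ms / cfg.step_ms))
    p_drive = cfg.drive_rate * cfg.step_ms / 1000.0
    max_spm = cfg.rate_ceiling * cfg.n_neurons * cfg.step_ms / 1000.0
    if isinstance(cfg, SOCConfig):
        rng = np.random.default_rng(seeds[1])
        V = _init_potentials(cfg.n_neurons, cfg.theta, rng)
        times, units, origin, _, aborted = _soc_driven_kernel(
            V, cfg.L, cfg.alpha, cfg.theta, p_drive, n_steps, max_spm,
            int(seeds[0]), 1, cfg.transient_steps)
        positions = lattice_positions(cfg.L)
    else:
        times, units, origin, _, aborted = _branching_driven_kernel(
            cfg.n_neurons, cfg.k, cfg.p_activation, p_drive, n_steps, max_spm,
            int(seeds[0]), 1, cfg.transient_steps)
        positions = None
    if aborted >= 0:
        raise RuntimeError(
            f"runaway activity: population rate exceeded "
            f"{cfg.rate_ceiling} Hz/unit at step {aborted}")
    keep = times >= cfg.transient_steps
    return SpikeRaster(
        times=(times[keep] - cfg.transient_steps) * cfg.step_ms,
        units=units[keep].astype(np.int64),
        n_units=cfg.n_neurons,
        duration=float(duration_ms),
        origin=origin[keep],
        unit_positions=positions,
        meta={"cfg": cfg, "seed": seed},
    )


def stationary_rate(cfg: Config, duration_ms: float = 200_000.0,
                    seed: Optional[int] = None) -> float:
    """Post-transient single-unit rate (Hz) of a driven configuration.

    Spikes are counted in the kernel without being stored, so this stays
    cheap even at high rates; runaway configurations (guarded by
    ``rate_ceiling``) return ``inf``.
    """
    if cfg.mode != "driven" or cfg.drive_rate <= 0:
        raise ValueError("stationary_rate requires driven mode with h > 0")
    seed = cfg.seed if seed is None else seed
    seeds = _derive_seeds(seed, 2)
    n_steps = int(round(cfg.transient_steps + duration_ms / cfg.step_ms))
    p_drive = cfg.drive_rate * cfg.step_ms / 1000.0
    max_spm = cfg.rate_ceiling * cfg.n_neurons * cfg.step_ms / 1000.0
    if isinstance(cfg, SOCConfig):
        rng = np.random.default_rng(seeds[1])
        V = _init_potentials(cfg.n_neurons, cfg.theta, rng)
        _, _, _, nkeep, aborted = _soc_driven_kernel(
            V, cfg.L, cfg.alpha, cfg.theta, p_drive, n_steps, max_spm,
            int(seeds[0]), 0, cfg.transient_steps)
    else:
        _, _, _, nkeep, aborted = _branching_driven_kernel(
            cfg.n_neurons, cfg.k, cfg.p_activation, p_drive, n_steps, max_spm,
            int(seeds[0]), 0, cfg.transient_steps)
    if aborted >= 0:
        return float("inf")
    return nkeep / (duration_ms / 1000.0) / cfg.n_neurons


def calibrate_drive(cfg: Config, alpha: float, target_rate: float,
                    tolerance: float = 0.02, seed: Optional[int] = None,
                    est_duration_ms: float = 200_000.0,
                    max_iter: int = 24) -> float:
    """Find the drive rate h (Hz/unit) that yields a target single-unit rate.

    Bisection on ``log h``; the stationary rate is monotone increasing in h,
    and since every input spike produces at least one spike, ``r(h) >= h``
    makes ``h = target_rate`` a valid upper bracket without evaluation.
    Each evaluation simulates ``est_duration_ms`` post-transient.  At
    ``alpha = 0`` the units are independent Poisson with ``r = h`` exactly,
    so the target is returned directly.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if alpha == 0.0:
        return target_rate
    seed = cfg.seed if seed is None else seed
    child = np.random.SeedSequence(seed).generate_state(max_iter + 1,
                                                        dtype=np.uint32)

    def rate_at(h: float, s: int) -> float:
        c = replace(cfg, alpha=alpha, drive_rate=h, mode="driven")
        return stationary_rate(c, est_duration_ms, seed=int(s))

    lo, hi = target_rate * 1e-5, target_rate
    r_lo = rate_at(lo, child[0])
    if r_lo > target_rate * (1 + tolerance):
        raise RuntimeError(
            f"bracketing failure: r({lo:.4g} Hz) = {r_lo:.4g} Hz "
            f"> target {target_rate} Hz")
    h = hi
    for i in range(max_iter):
        h = np.sqrt(lo * hi)
        r = rate_at(h, child[i + 1])
        if abs(r - target_rate) <= tolerance * target_rate:
            return float(h)
        if r > target_rate:
            hi = h
        else:
            lo = h
    return float(h)
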