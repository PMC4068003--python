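"""Unit and property tests for the lattice and branching simulators."""

import numpy as np
import pytest

from melange import (BranchingConfig, SOCConfig, SOCState, branching_step,
                     calibrate_drive, run_driven, run_sts, run_sts_raster,
                     soc_step)
from melange.simulators import _soc_sts_kernel


def _state(V, L=3):
    return SOCState(V=np.asarray(V, dtype=float))


class TestSOCStep:
    def test_quiescent_lattice_stays_quiescent(self):
        cfg = SOCConfig(L=3, alpha=1.0)
        st = _state(np.full(9, -0.5))
        new, spikers = soc_step(st, cfg)
        assert spikers.size == 0
        assert np.array_equal(new.V, st.V)
        assert new.t == st.t + 1

    def test_single_spike_update_rule(self):
        # one unit above threshold, alpha=1: it drops by 4, each of its 4
        # neighbours gains 1, nothing else spikes next step
        cfg = SOCConfig(L=3, alpha=1.0)
        V = np.full(9, -3.0)
        V[4] = 0.5
        new, spikers = soc_step(_state(V), cfg)
        assert list(spikers) == [4]
        assert new.V[4] == pytest.approx(-3.5)
        for nb in (1, 3, 5, 7):
            assert new.V[nb] == pytest.approx(-2.0)
        for corner in (0, 2, 6, 8):
            assert new.V[corner] == pytest.approx(-3.0)
        _, second = soc_step(new, cfg)
        assert second.size == 0

    def test_3x3_cascade_matches_hand_execution(self):
        # alpha=1, all V=-0.5, centre forced: hand-executed toppling gives
        # per-step spike counts [1, 4, 5] (centre; 4 edges; centre again
        # plus 4 corners) and then extinction
        cfg = SOCConfig(L=3, alpha=1.0)
        st = _state(np.full(9, -0.5))
        st, spk = soc_step(st, cfg, forced_units=[4])
        step_sizes = []
        while spk.size:
            step_sizes.append(int(spk.size))
            st, spk = soc_step(st, cfg)
        assert step_sizes == [1, 4, 5]
        assert sum(step_sizes) == 10

    @pytest.mark.parametrize("alpha", [1.0, 0.9, 0.5])
    def test_charge_bookkeeping(self, alpha):
        # potential removed from spikers equals 4; delivered = 4*alpha for
        # interior spikers, (3 or 2)*alpha at edges/corners; the balance of
        # sum(V) must match exactly
        rng = np.random.default_rng(7)
        cfg = SOCConfig(L=5, alpha=alpha)
        V = rng.uniform(-4, 1.5, size=25)
        st = _state(V, L=5)
        new, spikers = soc_step(st, cfg)
        rows, cols = np.divmod(spikers, 5)
        n_nb = ((rows > 0).astype(int) + (rows < 4).astype(int)
                + (cols > 0).astype(int) + (cols < 4).astype(int))
        expected_delta = alpha * n_nb.sum() - 4.0 * spikers.size
        assert new.V.sum() - st.V.sum() == pytest.approx(expected_delta)

    def test_forced_unit_above_threshold_is_unchanged(self):
        cfg = SOCConfig(L=3, alpha=0.5)
        V = np.full(9, -2.0)
        V[0] = 3.0
        new, spikers = soc_step(_state(V), cfg, forced_units=[0])
        assert 0 in spikers
        assert new.V[0] == pytest.approx(-1.0)  # 3 - 4, not theta+eps-4


class TestSTSCascades:
    def test_kernel_cascade_matches_reference_stepper(self):
        # the compiled STS kernel must reproduce the numpy reference
        # semantics exactly: same start unit, same size and duration
        L, kseed = 6, 1234
        rng = np.random.default_rng(99)
        V0 = rng.uniform(-4, 0, size=L * L)
        sizes, durs, _, _, _ = _soc_sts_kernel(
            V0.copy(), L, 1.0, 0.0, 1, 10 ** 7, kseed, 0, 0, 1)
        u0 = int(np.random.RandomState(kseed).randint(0, L * L))
        cfg = SOCConfig(L=L, alpha=1.0)
        st, spk = soc_step(SOCState(V=V0.copy()), cfg, forced_units=[u0])
        size = dur = 0
        while spk.size:
            size += spk.size
            dur += 1
            st, spk = soc_step(st, cfg)
        assert (size, dur) == (int(sizes[0]), int(durs[0]))

    def test_branching_alpha0_all_singletons(self):
        cs = run_sts(BranchingConfig(mode="STS", alpha=0.0), 500, seed=1)
        assert np.all(cs.sizes == 1)

    def test_branching_subcritical_mean_size_closed_form(self):
        # mean total cascade size of a subcritical branching process is
        # 1/(1 - alpha(1-p_diss)); use a large network so that same-target
        # collisions are negligible
        cfg = BranchingConfig(n_neurons=100_000, mode="STS", alpha=0.9,
                              p_diss=0.001)
        cs = run_sts(cfg, 100_000, seed=2)
        expected = 1.0 / (1.0 - 0.9 * (1.0 - 0.001))
        se = cs.sizes.std() / np.sqrt(cs.sizes.size)
        assert abs(cs.sizes.mean() - expected) < 3 * se

    def test_sts_sample_reproducible(self):
        cfg = SOCConfig(mode="STS", alpha=1.0, transient_avalanches=100)
        a = run_sts(cfg, 500, seed=3)
        b = run_sts(cfg, 500, seed=3)
        assert np.array_equal(a.sizes, b.sizes)
        assert np.array_equal(a.durations, b.durations)

    def test_sts_raster_has_long_gaps(self):
        raster = run_sts_raster(
            SOCConfig(mode="STS", alpha=1.0, transient_avalanches=200),
            200, gap_ms=5000.0, seed=4)
        gaps = np.diff(raster.times)
        assert (gaps >= 4999).sum() >= 150  # one long pause per avalanche


class TestBranchingStep:
    def test_alpha0_extinguishes(self):
        cfg = BranchingConfig(alpha=0.0)
        rng = np.random.default_rng(0)
        assert branching_step([1, 2, 3], cfg, rng).size == 0

    def test_offspring_mean_matches_alpha(self):
        # empirical offspring per active unit = alpha(1-p_diss) within 3 SE;
        # large network so deduplication does not bite
        cfg = BranchingConfig(n_neurons=10 ** 6, alpha=0.8, p_diss=0.001)
        rng = np.random.default_rng(5)
        total_off, total_act = 0, 0
        active = rng.integers(0, cfg.n_neurons, size=2000)
        for _ in range(100):
            nxt = branching_step(active, cfg, rng)
            total_off += nxt.size
            total_act += active.size
            active = nxt if nxt.size else rng.integers(0, cfg.n_neurons,
                                                       size=2000)
        p = cfg.alpha * (1 - cfg.p_diss)
        se = np.sqrt(cfg.k * (p / cfg.k) * (1 - p / cfg.k) * total_act) / total_act
        assert abs(total_off / total_act - p) < 3 * se


class TestDriven:
    def test_alpha0_is_poisson(self):
        # independent Poisson units at r = h: ISI CV ~ 1, count Fano ~ 1
        cfg = SOCConfig(mode="driven", alpha=0.0, drive_rate=5.0,
                        transient_steps=1000)
        raster = run_driven(cfg, 200_000, seed=6)
        assert raster.unit_rate == pytest.approx(5.0, rel=0.05)
        isi = np.diff(np.sort(raster.times[raster.units == 7]))
        assert isi.std() / isi.mean() == pytest.approx(1.0, abs=0.1)
        counts = np.bincount((raster.times // 1000).astype(int), minlength=200)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)
        assert np.all(raster.origin == 1)  # every spike externally driven

    def test_input_spike_rate_matches_drive(self):
        cfg = SOCConfig(mode="driven", alpha=0.9, drive_rate=1.0,
                        transient_steps=20_000)
        raster = run_driven(cfg, 200_000, seed=7)
        n_inputs = int(raster.origin.sum())
        expect = cfg.drive_rate * cfg.n_neurons * 200.0  # h * N * T(s)
        assert abs(n_inputs - expect) < 4 * np.sqrt(expect)

    def test_fixed_seed_bit_identical(self):
        cfg = BranchingConfig(mode="driven", alpha=0.95, drive_rate=0.5,
                              transient_steps=5000)
        a = run_driven(cfg, 50_000, seed=8)
        b = run_driven(cfg, 50_000, seed=8)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.units, b.units)
        assert np.array_equal(a.origin, b.origin)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            run_driven(SOCConfig(mode="STS"), 1000)
        with pytest.raises(ValueError):
            run_sts(SOCConfig(mode="driven", drive_rate=1.0), 10)


class TestCalibration:
    def test_alpha0_poisson_limit(self):
        cfg = SOCConfig(mode="driven")
        assert calibrate_drive(cfg, 0.0, target_rate=5.0) == 5.0

    def test_calibrated_rate_hits_target(self):
        cfg = BranchingConfig(mode="driven", transient_steps=30_000)
        h = calibrate_drive(cfg, 0.9, target_rate=5.0, seed=9,
                            est_duration_ms=100_000.0)
        # subcritical branching amplifies by 1/(1-alpha(1-p_diss)) ~ 9.9
        assert h == pytest.approx(5.0 / 9.911, rel=0.1)

    def test_calibrated_drive_nonincreasing_in_alpha(self):
        # at fixed target rate, stronger coupling needs less drive
        cfg = SOCConfig(mode="driven", transient_steps=30_000)
        hs = [calibrate_drive(cfg, a, target_rate=5.0, seed=10,
                              est_duration_ms=60_000.0)
              for a in (0.0, 0.5, 0.9, 0.99, 1.0)]
        assert all(h1 >= h2 * 0.95 for h1, h2 in zip(hs, hs[1:]))
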