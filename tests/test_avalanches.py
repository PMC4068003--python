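"""Avalanche statistics: direct examples, Poisson closed forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melange import (BinnedCounts, SpikeRaster, avalanches_at, bin_spikes,
                     estimate_sigma, extract_avalanches, f1_curve, log_bin,
                     mean_iei, mean_size, size_distribution, SizeDistribution)
from conftest import poisson_mean_size, poisson_sigma_star


def _raster(times, duration, n_units=1):
    times = np.asarray(times, dtype=float)
    return SpikeRaster(times=times, units=np.zeros(times.size, dtype=int),
                       n_units=n_units, duration=duration)


class TestBinning:
    def test_half_open_bins(self):
        counts = bin_spikes(_raster([0.2, 0.7, 3.1], 4.0), 1.0)
        assert list(counts.counts) == [2, 0, 0, 1]

    def test_trailing_partial_bin_dropped(self):
        counts = bin_spikes(_raster([0.5, 9.5], 10.0), 3.0)
        assert counts.n_bins == 3
        assert counts.counts.sum() == 1  # the 9.5 ms spike is in the tail

    def test_empty_raster_errors(self):
        with pytest.raises(ValueError):
            bin_spikes(_raster([], 10.0), 1.0)

    def test_below_resolution_errors(self):
        with pytest.raises(ValueError):
            bin_spikes(_raster([1.0], 10.0), 1e-5)

    def test_poisson_empty_bin_fraction(self, poisson_raster):
        # void probability of a Poisson process: P(empty) = exp(-R*bs)
        for bs in (2.0, 4.0, 8.0):
            counts = bin_spikes(poisson_raster, bs)
            lam = poisson_raster.population_rate * bs / 1000.0
            frac = (counts.counts == 0).mean()
            se = np.sqrt(np.exp(-lam) * (1 - np.exp(-lam)) / counts.n_bins)
            assert abs(frac - np.exp(-lam)) < 4 * se


class TestExtraction:
    def test_runs_of_nonzero_bins(self):
        aset = extract_avalanches(
            BinnedCounts(np.array([2, 1, 0, 3, 1, 0, 0, 1]), 1.0))
        assert list(aset.sizes) == [3, 4, 1]
        assert list(aset.boundary) == [True, False, True]

    def test_all_bins_nonzero_single_avalanche(self):
        aset = extract_avalanches(BinnedCounts(np.array([1, 2, 3]), 1.0))
        assert list(aset.sizes) == [6]

    def test_mean_size_example(self):
        aset = extract_avalanches(
            BinnedCounts(np.array([2, 1, 0, 3, 1, 0, 0, 1]), 1.0))
        assert mean_size(aset) == pytest.approx(8 / 3)

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=1,
                    max_size=200))
    @settings(deadline=None, max_examples=100)
    def test_partition_property(self, counts):
        # every spike belongs to exactly one avalanche
        aset = extract_avalanches(BinnedCounts(np.array(counts), 1.0))
        assert aset.sizes.sum() == sum(counts)
        assert np.all(aset.sizes >= 1)

    def test_monotone_merging(self, poisson_raster):
        # on a doubling bin grid the number of avalanches never increases
        n = [avalanches_at(poisson_raster, bs).n_avalanches
             for bs in (1, 2, 4, 8, 16, 32, 64)]
        assert all(a >= b for a, b in zip(n, n[1:]))

    def test_poisson_size1_rate(self, poisson_raster):
        # a size-1 avalanche is one spike in a bin flanked by empty bins:
        # rate = R * exp(-3 R bs) per unit time
        bs = 4.0
        R = poisson_raster.population_rate / 1000.0  # spikes per ms
        aset = avalanches_at(poisson_raster, bs)
        n1 = (aset.sizes == 1).sum()
        expect = R * np.exp(-3 * R * bs) * poisson_raster.duration
        assert abs(n1 - expect) < 4 * np.sqrt(expect)

    def test_poisson_mean_size_closed_form(self, poisson_raster):
        for bs in (2.0, 4.0, 8.0):
            lam = poisson_raster.population_rate * bs / 1000.0
            aset = avalanches_at(poisson_raster, bs)
            se = aset.sizes.std() / np.sqrt(aset.n_avalanches)
            assert abs(mean_size(aset) - poisson_mean_size(lam)) < 4 * se

    def test_boundary_avalanche_share_negligible(self, poisson_raster):
        aset = avalanches_at(poisson_raster, 4.0)
        with_b = aset.sizes.mean()
        without = aset.interior().mean()
        assert abs(with_b - without) / with_b < 0.01

    def test_phase_shift_changes_little(self, poisson_raster):
        shifted = SpikeRaster(times=poisson_raster.times + 0.37,
                              units=poisson_raster.units,
                              n_units=poisson_raster.n_units,
                              duration=poisson_raster.duration + 1.0)
        for bs in (2.0, 8.0):
            a = mean_size(avalanches_at(poisson_raster, bs))
            b = mean_size(avalanches_at(shifted, bs))
            assert a == pytest.approx(b, rel=0.05)


class TestIEI:
    def test_definition(self):
        assert mean_iei(_raster([1, 3, 5, 7, 9], 10.0)) == pytest.approx(2.0)

    def test_matched_to_rate(self, poisson_raster):
        assert mean_iei(poisson_raster) == pytest.approx(
            1000.0 / poisson_raster.population_rate)


class TestSigmaStar:
    def test_worked_example(self):
        # counts [2,4,0,1,1]: ratios 2, 0, nd, 1 -> mean 1.0
        est = estimate_sigma(BinnedCounts(np.array([2, 4, 0, 1, 1]), 1.0))
        assert est.sigma == pytest.approx(1.0)
        assert est.n_defined == 3

    def test_constant_counts(self):
        est = estimate_sigma(BinnedCounts(np.full(50, 7), 1.0))
        assert est.sigma == pytest.approx(1.0)

    def test_all_predecessors_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_sigma(BinnedCounts(np.array([0, 0, 0, 1]), 1.0))

    def test_poisson_closed_form(self, poisson_raster):
        # independent bins: sigma* = lam * E[1/n | n>0], -> 1 for large bins
        for bs in (4.0, 16.0, 64.0):
            lam = poisson_raster.population_rate * bs / 1000.0
            est = estimate_sigma(bin_spikes(poisson_raster, bs),
                                 keep_ratios=True)
            se = est.ratios.std() / np.sqrt(est.n_defined)
            assert abs(est.sigma - poisson_sigma_star(lam)) < 4 * se
        assert abs(estimate_sigma(bin_spikes(poisson_raster, 256.0)).sigma
                   - 1.0) < 0.05


class TestF1Curve:
    def test_normalized_at_one_iei(self, poisson_raster):
        curve = f1_curve(poisson_raster, [0.5, 1.0, 2.0])
        assert curve[1.0] == 1.0

    def test_missing_normalization_point_errors(self, poisson_raster):
        with pytest.raises(ValueError):
            f1_curve(poisson_raster, [0.5, 2.0])

    def test_poisson_exponential_decay(self, poisson_raster):
        # f(s=1, bs) ~ exp(-3 R bs): each <IEI> step multiplies by e^-3
        curve = f1_curve(poisson_raster, [1.0, 2.0, 3.0])
        assert curve[2.0] == pytest.approx(np.exp(-3.0), rel=0.15)
        assert curve[3.0] == pytest.approx(np.exp(-6.0), rel=0.4)


class TestLogBin:
    def test_exact_power_law_stays_power_law(self):
        support = np.arange(1, 2001, dtype=float)
        dist = SizeDistribution(support=support,
                                frequency=1e6 * support ** -1.5)
        lb = log_bin(dist, bins_per_decade=10)
        slope = np.polyfit(np.log10(lb.support), np.log10(lb.frequency), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.02)

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(1, 500, size=1000)
        support, freq = np.unique(sizes, return_counts=True)
        dist = SizeDistribution(support=support.astype(float),
                                frequency=freq.astype(float))
        lb = log_bin(dist, 8)
        which = np.searchsorted(lb.bin_edges, lb.support, side="right") - 1
        widths = np.diff(lb.bin_edges)[which]
        assert (lb.frequency * widths).sum() == pytest.approx(1000)

    def test_empty_distribution_errors(self):
        with pytest.raises(ValueError):
            log_bin(SizeDistribution(support=np.array([]),
                                     frequency=np.array([])))
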