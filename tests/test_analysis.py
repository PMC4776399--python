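"""OKR-gain estimation and granule-cell reproducibility index."""

import numpy as np
import pytest

from okrsim.analysis import (
    epsp_trace,
    epsp_traces,
    fit_cosine,
    measure_gain,
    reproducibility_index,
    reproducibility_over_cycles,
)
from okrsim.stimulus import RateLaw, sample_poisson


def cosine_poisson_train(baseline, amplitude, n_cycles, rng, period_ms=6000.0):
    """Inhomogeneous Poisson spikes with rate B + A cos(2 pi t / T)."""
    t = np.arange(int(n_cycles * period_ms))
    rate = baseline + amplitude * np.cos(2 * np.pi * t / period_ms)
    p = np.clip(rate, 0, None) / 1000.0
    return t[rng.random(t.size) < p].astype(float)


class TestGain:
    def test_exact_cosine_recovered_to_machine_precision(self):
        t_centers = (np.arange(60) + 0.5) * 100.0
        hist = 40.0 + 12.5 * np.cos(2 * np.pi * t_centers / 6000.0 + 0.7)
        amp, base, phase = fit_cosine(hist)
        assert amp == pytest.approx(12.5, abs=1e-9)
        assert base == pytest.approx(40.0, abs=1e-9)
        assert phase == pytest.approx(0.7, abs=1e-9)

    def test_homogeneous_poisson_has_near_zero_amplitude(self):
        rng = np.random.default_rng(0)
        spikes = cosine_poisson_train(40.0, 0.0, 20, rng)
        g = measure_gain(spikes, n_cycles=20)
        # amplitude SE ~ sqrt(2 B / T_total)
        se = np.sqrt(2 * 40.0 / (20 * 6.0))
        assert g.amplitude < 4 * se
        assert g.baseline == pytest.approx(40.0, abs=4 * se)

    def test_modulated_poisson_round_trip(self):
        rng = np.random.default_rng(1)
        spikes = cosine_poisson_train(40.0, 15.0, 10, rng)
        g = measure_gain(spikes, n_cycles=10)
        se = np.sqrt(2 * 40.0 / (10 * 6.0))
        assert g.amplitude == pytest.approx(15.0, abs=3 * se)
        assert abs(g.phase_offset) < 0.3

    def test_estimator_unbiased_across_seeds(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spikes = cosine_poisson_train(40.0, 15.0, 10, rng)
            errs.append(measure_gain(spikes, n_cycles=10).amplitude - 15.0)
        se_mean = np.sqrt(2 * 40.0 / (10 * 6.0)) / np.sqrt(20)
        assert abs(np.mean(errs)) < 4 * se_mean

    def test_amplitude_nonnegative_by_construction(self):
        rng = np.random.default_rng(3)
        spikes = cosine_poisson_train(30.0, 5.0, 5, rng)
        assert measure_gain(spikes, n_cycles=5).amplitude >= 0.0

    def test_empty_spikes_warn_and_zero(self):
        with pytest.warns(UserWarning):
            g = measure_gain(np.array([]), n_cycles=10)
        assert g.amplitude == 0.0 and g.baseline == 0.0

    def test_bin_must_divide_period(self):
        with pytest.raises(ValueError):
            measure_gain(np.array([1.0]), n_cycles=1, bin_ms=70.0)

    def test_histogram_units_spikes_per_second(self):
        # one spike per bin per cycle -> 10 spikes/s at 100-ms bins
        spikes = np.concatenate(
            [np.arange(60) * 100.0 + 6000.0 * c for c in range(4)]
        )
        g = measure_gain(spikes, n_cycles=4)
        np.testing.assert_allclose(g.histogram, 10.0)


class TestEpspTrace:
    def test_single_spike_exponential(self):
        z = epsp_trace([10.0], 60.0, tau_ms=8.3)
        t = np.arange(60.0)
        expected = np.where(t >= 10.0, np.exp(-(t - 10.0) / 8.3), 0.0)
        np.testing.assert_allclose(z, expected, rtol=1e-12)

    def test_no_spikes_zero(self):
        assert np.all(epsp_trace([], 100.0) == 0.0)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.choice(500, size=40, replace=False)).astype(float)
        z = epsp_trace(spikes, 500.0)
        t = np.arange(500.0)
        brute = np.zeros(500)
        for s in spikes:
            brute += np.where(t >= s, np.exp(-(t - s) / 8.3), 0.0)
        np.testing.assert_allclose(z, brute, rtol=1e-9)

    def test_stacked_traces_match_single(self):
        rng = np.random.default_rng(8)
        trains = [np.sort(rng.choice(300, 20, replace=False)).astype(float) for _ in range(5)]
        stacked = epsp_traces(trains, 300.0)
        for j, tr in enumerate(trains):
            np.testing.assert_allclose(stacked[j], epsp_trace(tr, 300.0), rtol=1e-12)


class TestReproducibility:
    def test_single_active_cell_identical_cycles_gives_one(self):
        z = epsp_trace([5.0, 50.0], 100.0)[None, :]
        r = reproducibility_index(z, z)
        active = z[0] > 0
        np.testing.assert_allclose(r[active], 1.0, rtol=1e-12)

    def test_identical_uniform_cells_give_one_over_n(self):
        # the printed product-of-sums normalization gives 1/N for N
        # identical cells — the documented peculiarity of this index
        for n in (2, 10, 64):
            z = np.ones((n, 30))
            np.testing.assert_allclose(
                reproducibility_index(z, z), 1.0 / n, rtol=1e-12
            )

    def test_cosine_normalization_gives_one_for_identical(self):
        rng = np.random.default_rng(2)
        z = rng.random((16, 40))
        r = reproducibility_index(z, z, normalization="cosine")
        np.testing.assert_allclose(r, 1.0, rtol=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((32, 50)), rng.random((32, 50))
        r = reproducibility_index(a, b)
        t = 17
        brute = (a[:, t] * b[:, t]).sum() / (a[:, t].sum() * b[:, t].sum())
        assert r[t] == pytest.approx(brute, rel=1e-12)

    def test_zero_denominator_missing_value(self):
        a = np.zeros((3, 5))
        r = reproducibility_index(a, a)
        assert np.isnan(r).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reproducibility_index(np.ones((2, 5)), np.ones((3, 5)))

    @staticmethod
    def _modulated_trains(n_cells, n_cycles, rng, jitter=True):
        """Cells share a cyclostationary rate profile; noise is private."""
        period = 1000.0
        t = np.arange(int(n_cycles * period))
        rate = 30.0 * (1 + np.sin(2 * np.pi * t / period)) / 1000.0
        return [t[rng.random(t.size) < rate].astype(float) for _ in range(n_cells)]

    def test_identical_patterns_beat_resampled_patterns(self):
        rng = np.random.default_rng(4)
        period, cycles = 1000.0, 6
        base = self._modulated_trains(40, 1, rng)
        # identical pattern repeated each cycle
        frozen = [
            np.concatenate([tr + c * period for c in range(cycles)]) for tr in base
        ]
        frozen_r = reproducibility_over_cycles(frozen, period, cycles).grand_mean
        resampled = self._modulated_trains(40, cycles, rng)
        resampled_r = reproducibility_over_cycles(resampled, period, cycles).grand_mean
        assert frozen_r > resampled_r

    def test_population_trace_correlation_detects_locking(self):
        # N x R (product form) is the cycle-to-cycle correlation ratio of
        # the population-summed trace: stimulus-locked populations sit
        # above the independence level 1, fully random ones at ~1
        rng = np.random.default_rng(5)
        period, cycles = 1000.0, 6
        base = self._modulated_trains(60, 1, rng)
        frozen = [
            np.concatenate([tr + c * period for c in range(cycles)]) for tr in base
        ]
        r_frozen = reproducibility_over_cycles(frozen, period, cycles)
        resampled = self._modulated_trains(60, cycles, rng)
        r_resampled = reproducibility_over_cycles(resampled, period, cycles)
        assert np.nanmean(r_frozen.mean) * 60 > 1.1
        assert np.nanmean(r_resampled.mean) * 60 < np.nanmean(r_frozen.mean) * 60

    def test_pair_count(self):
        rng = np.random.default_rng(6)
        trains = self._modulated_trains(10, 11, rng)
        res = reproducibility_over_cycles(trains, 1000.0, 11)
        assert res.n_pairs == 10
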