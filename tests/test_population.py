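from collections import Counter

import numpy as np
import pytest

from pacwm.population import (N_SLIDING_BINS, greedy_decoding,
                              noise_correlation, noise_correlation_null,
                              remove_noise_correlations,
                              rt_split_correlations, signal_noise_geometry,
                              sliding_counts, _fold_angle_deg)
from pacwm.synthetic import (simulate_population_rates,
                             simulate_two_neuron_geometry)


class TestSlidingCounts:
    def test_101_bins_cover_maintenance(self):
        assert N_SLIDING_BINS == 101
        counts = sliding_counts(np.array([10.5]), np.array([10.0]))
        assert counts.shape == (1, 101)

    def test_constant_rate_unit_row_means(self, rng):
        rate = 20.0
        onsets = np.arange(5) * 10.0
        ts = np.sort(rng.uniform(0, 50, int(rate * 50)))
        counts = sliding_counts(ts, onsets)
        assert counts.mean() == pytest.approx(rate * 0.2, rel=0.15)

    def test_empty_unit_zero_matrix(self):
        counts = sliding_counts(np.array([]), np.arange(3) * 10.0)
        assert counts.shape == (3, 101)
        assert np.all(counts == 0)


def _correlated_counts(rng, n_trials=40, n_bins=101, shared=2.0, noise=1.0):
    g = shared * rng.standard_normal((n_trials, n_bins))
    a = 5 + g + noise * rng.standard_normal((n_trials, n_bins))
    b = 5 + g + noise * rng.standard_normal((n_trials, n_bins))
    return a, b


class TestNoiseCorrelation:
    def test_independent_units_inside_null_band(self, rng):
        a = rng.poisson(3, (40, 101)).astype(float)
        b = rng.poisson(3, (40, 101)).astype(float)
        labels = np.repeat([0, 1], 20)
        r = noise_correlation(a, b)
        null = noise_correlation_null(a, b, labels, n_shuffle=200, rng=rng)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= r <= hi

    def test_shared_gain_pairs_exceed_null(self, rng):
        a, b = _correlated_counts(rng)
        labels = np.repeat([0, 1], 20)
        r = noise_correlation(a, b)
        null = noise_correlation_null(a, b, labels, n_shuffle=200, rng=rng)
        assert r > np.percentile(null, 99)

    def test_zero_variance_trials_skipped(self, rng):
        a = rng.poisson(3, (10, 101)).astype(float)
        b = rng.poisson(3, (10, 101)).astype(float)
        a[0] = 0.0
        r = noise_correlation(a, b)
        assert np.isfinite(r)


class TestRemoveNoiseCorrelations:
    def test_per_category_multisets_preserved_exactly(self, rng):
        labels = rng.integers(0, 5, 60)
        counts = [rng.poisson(4, (60, 7)).astype(float) for _ in range(3)]
        shuffled = remove_noise_correlations(counts, labels, rng)
        for orig, shuf in zip(counts, shuffled):
            for lab in range(5):
                m = labels == lab
                c_orig = Counter(map(tuple, orig[m]))
                c_shuf = Counter(map(tuple, shuf[m]))
                assert c_orig == c_shuf

    def test_category_means_unchanged_exactly(self, rng):
        labels = rng.integers(0, 3, 30)
        counts = [rng.standard_normal((30, 4)) for _ in range(2)]
        shuffled = remove_noise_correlations(counts, labels, rng)
        for orig, shuf in zip(counts, shuffled):
            for lab in range(3):
                m = labels == lab
                np.testing.assert_allclose(orig[m].mean(0), shuf[m].mean(0))

    def test_drives_pairwise_r_toward_zero(self, rng):
        a, b = _correlated_counts(rng)
        labels = np.repeat([0, 1], 20)
        r_before = noise_correlation(a, b)
        a2, b2 = remove_noise_correlations([a, b], labels, rng)
        r_after = noise_correlation(a2, b2)
        assert r_before > 0.5
        assert abs(r_after) < 0.2

    def test_single_trial_category_identity(self, rng):
        labels = np.array([0, 1, 1])
        counts = [np.arange(6).reshape(3, 2).astype(float)]
        shuffled = remove_noise_correlations(counts, labels, rng)
        np.testing.assert_array_equal(shuffled[0][0], counts[0][0])


class TestGreedyDecoding:
    def test_untuned_ensemble_near_chance(self, rng):
        rates, labels, _ = simulate_population_rates(
            n_trials_per_cat=30, n_tuned=0, n_untuned=5, shared_sd=0.0,
            distribution="poisson", rng=rng)
        res = greedy_decoding(rates, labels, n_rep=15, rng=rng)
        assert res.chance == pytest.approx(0.2)
        assert abs(res.accuracy_curve[-1] - 0.2) < 0.12

    def test_noiseless_tuned_unit_perfect(self, rng):
        labels = np.repeat(np.arange(5), 10)
        rates = np.column_stack([labels.astype(float),
                                 rng.standard_normal(50)])
        res = greedy_decoding(rates, labels, n_rep=10, rng=rng)
        assert res.max_acc > 0.95
        assert res.ensemble_order[0] == 0  # greedy finds the coding unit first

    def test_enhancing_correlations_beat_removed(self, rng):
        rates, labels, _ = simulate_population_rates(rng=rng)
        intact = greedy_decoding(rates, labels, n_rep=15, rng=np.random.default_rng(5))
        removed = greedy_decoding(rates, labels, n_rep=15, remove_corr=True,
                                  rng=np.random.default_rng(5))
        assert intact.max_acc > removed.max_acc

    def test_curve_length_and_order(self, rng):
        rates, labels, _ = simulate_population_rates(
            n_tuned=2, n_untuned=2, rng=rng)
        res = greedy_decoding(rates, labels, n_rep=8, rng=rng)
        assert len(res.accuracy_curve) == 4
        assert sorted(res.ensemble_order) == [0, 1, 2, 3]
        assert res.max_size >= 1


class TestGeometry:
    def test_fold_angle_basics(self):
        assert _fold_angle_deg(np.r_[1.0, 0.0], np.r_[0.0, 1.0]) == \
            pytest.approx(90.0)
        assert _fold_angle_deg(np.r_[1.0, 0.0], np.r_[-1.0, 0.0]) == \
            pytest.approx(0.0)  # folded: sign irrelevant

    def test_orthogonal_construction_near_90(self, rng):
        # category signal along unit 1, dominant noise along unit 2
        labels = np.repeat([0, 1], 150)
        rates = np.zeros((300, 2))
        rates[:, 0] = 3.0 * labels + 0.2 * rng.standard_normal(300)
        rates[:, 1] = 4.0 * rng.standard_normal(300)
        geo = signal_noise_geometry(rates, labels, n_rep=10, rng=rng)
        assert geo.angle > 85.0

    def test_aligned_construction_small_angle(self, rng):
        # signal and dominant shared noise both along (1, 1): the angle
        # collapses (information-limiting regime)
        labels = np.repeat([0, 1], 150)
        shared = 3.0 * rng.standard_normal(300)
        rates = np.zeros((300, 2))
        rates[:, 0] = 2.0 * labels + shared + 0.3 * rng.standard_normal(300)
        rates[:, 1] = 2.0 * labels + shared + 0.3 * rng.standard_normal(300)
        geo = signal_noise_geometry(rates, labels, n_rep=10, rng=rng)
        assert geo.angle < 45.0

    def test_two_neuron_enhancing_regime_directions(self):
        rates, labels = simulate_two_neuron_geometry(
            offset=2.0, noise_sd=0.5, shared_sd=3.0, rng=7)
        gi = signal_noise_geometry(rates, labels, n_rep=20,
                                   rng=np.random.default_rng(1))
        gr = signal_noise_geometry(rates, labels, n_rep=20, remove_corr=True,
                                   rng=np.random.default_rng(1))
        assert gi.angle > gr.angle
        assert gr.projection_sd > gi.projection_sd

    def test_no_shared_noise_angles_similar(self):
        rates, labels = simulate_two_neuron_geometry(
            offset=2.0, noise_sd=1.0, shared_sd=0.0, rng=9)
        gi = signal_noise_geometry(rates, labels, n_rep=20,
                                   rng=np.random.default_rng(2))
        gr = signal_noise_geometry(rates, labels, n_rep=20, remove_corr=True,
                                   rng=np.random.default_rng(2))
        assert abs(gi.angle - gr.angle) < 8.0

    def test_untuned_two_class_chance(self, rng):
        rates, labels = simulate_two_neuron_geometry(
            offset=0.0, noise_sd=1.0, shared_sd=0.0, rng=rng)
        res = greedy_decoding(rates, labels, n_rep=15, rng=rng)
        assert abs(res.accuracy_curve[-1] - 0.5) < 0.1


class TestRTSplit:
    def test_rt_coupled_gain_recovered(self, rng):
        n_trials, n_bins = 40, 101
        fast = np.zeros(n_trials, bool)
        fast[:20] = True
        pairs = []
        for _ in range(12):
            shared = rng.standard_normal((n_trials, n_bins))
            shared[~fast] = 0.0  # co-fluctuations only in fast trials
            a = 5 + 2 * shared + rng.standard_normal((n_trials, n_bins))
            b = 5 + 2 * shared + rng.standard_normal((n_trials, n_bins))
            pairs.append((a, b))
        df = rt_split_correlations(pairs, fast, ~fast)
        assert len(df) == 12
        assert df["delta"].mean() > 0.2

    def test_rt_independent_centred_on_zero(self, rng):
        fast = np.zeros(30, bool)
        fast[:15] = True
        pairs = [(rng.poisson(4, (30, 101)).astype(float),
                  rng.poisson(4, (30, 101)).astype(float)) for _ in range(10)]
        df = rt_split_correlations(pairs, fast, ~fast)
        assert abs(df["delta"].mean()) < 0.05

    def test_min_trials_exclusion(self, rng):
        fast = np.zeros(6, bool)
        fast[:2] = True
        pairs = [(rng.poisson(4, (6, 101)).astype(float),
                  rng.poisson(4, (6, 101)).astype(float))]
        df = rt_split_correlations(pairs, fast, ~fast, min_trials=5)
        assert len(df) == 0
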