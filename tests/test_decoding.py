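"""Decoders, saturating fit, PCA trajectories, clustering, correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import fearcode as fc
from fearcode.decoding import SaturatingModel, _saturating


class TestConstructCsWindows:
    def test_intervals_disjoint_and_sized(self):
        idx = fc.construct_cs_windows(300, 10.0, n_intervals=10,
                                      interval_s=0.5, rng=0)
        assert idx.size == 50
        assert np.unique(idx).size == 50  # pairwise disjoint
        assert idx.min() >= 0 and idx.max() < 300
        assert (np.diff(idx) > 0).all()   # order-preserving concatenation

    def test_single_sample_intervals_at_2hz(self):
        # 30-s window at 2 Hz = 60 samples; 10 x 0.5-s intervals = 10 samples
        idx = fc.construct_cs_windows(60, 2.0, rng=1)
        assert idx.size == 10
        assert np.unique(idx).size == 10

    def test_insufficient_room_is_error(self):
        with pytest.raises(ValueError):
            fc.construct_cs_windows(8, 2.0, n_intervals=10, interval_s=0.5)

    def test_deterministic_given_seed(self):
        a = fc.construct_cs_windows(300, 10.0, rng=7)
        b = fc.construct_cs_windows(300, 10.0, rng=7)
        np.testing.assert_array_equal(a, b)


def _expected_coinflip_f1(fold_sizes):
    """Enumeration oracle: expected F1 of uniformly random predictions on
    balanced folds with ``k`` positive and ``k`` negative samples."""
    out = []
    for k in fold_sizes:
        total, count = 0.0, 0
        for preds in itertools.product([0, 1], repeat=2 * k):
            tp = sum(preds[:k])
            fp = sum(preds[k:])
            fn = k - tp
            total += 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            count += 1
        out.append(total / count)
    return np.mean(out)


class TestDecodeCsAstro:
    def test_separable_fixture_beats_null(self):
        cfg = fc.SynthConfig(seed=77, n_trials=6, fraction_positive=1.0,
                             effect_size=8.0, n_cells=30)
        cm, sched, _ = fc.generate_cell_session(cfg)
        r = fc.decode_cs_astro(cm.data, cm.sampling_rate,
                               sched.onsets("CS_onset"),
                               n_constructions=30, n_shuffle=60, seed=0)
        assert r.observed_f1 > 0.9
        assert r.p_value < 0.05

    def test_null_data_inside_shuffle_band(self):
        cfg = fc.SynthConfig(seed=101, n_trials=6, effect_size=0.0, n_cells=20)
        cm, sched, _ = fc.generate_cell_session(cfg)
        r = fc.decode_cs_astro(cm.data, cm.sampling_rate,
                               sched.onsets("CS_onset"),
                               n_constructions=15, n_shuffle=60, seed=0)
        lo, hi = r.null_band
        assert lo <= r.observed_f1 <= hi

    def test_shuffle_null_mean_near_chance(self):
        """Shuffle-null mean F1 matches the enumeration oracle for
        coin-flip predictions on the same fold structure (within 0.05)."""
        cfg = fc.SynthConfig(seed=55, n_trials=6, effect_size=0.0, n_cells=15)
        cm, sched, _ = fc.generate_cell_session(cfg)
        r = fc.decode_cs_astro(cm.data, cm.sampling_rate,
                               sched.onsets("CS_onset"),
                               n_constructions=10, n_shuffle=80, seed=2)
        # 6 trials in 5 folds: four folds of 1 trial, one of 2 trials
        chance = _expected_coinflip_f1([1, 1, 1, 1, 2])
        assert abs(r.null_f1.mean() - chance) < 0.05

    def test_too_few_trials_rejected(self):
        cfg = fc.SynthConfig(seed=1, n_trials=3, n_cells=5)
        cm, sched, _ = fc.generate_cell_session(cfg)
        with pytest.raises(ValueError):
            fc.decode_cs_astro(cm.data, cm.sampling_rate,
                               sched.onsets("CS_onset"))

    def test_bitwise_reproducible(self):
        cfg = fc.SynthConfig(seed=8, n_trials=5, n_cells=10, effect_size=1.0,
                             fraction_positive=0.5)
        cm, sched, _ = fc.generate_cell_session(cfg)
        args = (cm.data, cm.sampling_rate, sched.onsets("CS_onset"))
        kw = dict(n_constructions=5, n_shuffle=10, seed=3)
        a, b = fc.decode_cs_astro(*args, **kw), fc.decode_cs_astro(*args, **kw)
        assert a.observed_f1 == b.observed_f1
        np.testing.assert_array_equal(a.null_f1, b.null_f1)


def _mouse_sessions(gain_b, n_per_group=4, seed0=500):
    sessions = []
    for m in range(2 * n_per_group):
        gain = 1.0 if m < n_per_group else gain_b
        cfg = fc.SynthConfig(seed=seed0 + m, n_cells=20, n_trials=5,
                             fraction_positive=0.4, fraction_negative=0.2,
                             effect_size=4.0, group_gain=gain)
        cm, sched, truth = fc.generate_cell_session(cfg)
        sessions.append(fc.MouseSession(cm, "veh" if m < n_per_group else "cno",
                                        categories=truth.category))
    return sessions


class TestDecodeGroup:
    def test_disjoint_groups_decoded_perfectly(self):
        r = fc.decode_group(_mouse_sessions(gain_b=0.0), "mean_pos",
                            n_shuffle=20, seed=0)
        assert r.observed_f1 == pytest.approx(1.0)

    def test_identical_groups_inside_null_band(self):
        r = fc.decode_group(_mouse_sessions(gain_b=1.0, seed0=900), "mean_pos",
                            n_shuffle=60, seed=1)
        lo, hi = r.null_band
        assert lo <= r.observed_f1 <= hi

    def test_every_feature_runs(self):
        sessions = _mouse_sessions(gain_b=0.0, n_per_group=2)
        for feature in fc.decoding.GROUP_FEATURES:
            r = fc.decode_group(sessions, feature, n_shuffle=5, seed=0)
            assert 0.0 <= r.observed_f1 <= 1.0

    def test_single_mouse_group_rejected(self):
        sessions = _mouse_sessions(gain_b=0.0, n_per_group=2)[1:]
        with pytest.raises(ValueError):
            fc.decode_group(sessions, "mean_pos")


@pytest.fixture(scope="module")
def curve():
    cfg = fc.SynthConfig(seed=9, n_trials=6, fraction_positive=0.4,
                         effect_size=3.0, n_cells=40)
    cm, _, _ = fc.generate_cell_session(cfg)
    return fc.decode_cs_vs_popsize(cm, sizes=np.arange(2, 21, 2),
                                   n_reps=8, n_shuffle_reps=8, seed=0)


class TestDecodeVsPopsize:
    def test_performance_increases_with_size(self, curve):
        rho = stats.spearmanr(curve.sizes, curve.means).statistic
        assert rho > 0

    def test_shuffle_curve_near_chance_on_null_data(self):
        """With no CS-locked signal, both the observed and shuffle curves sit
        at the coin-flip chance level predicted by the enumeration oracle."""
        cfg = fc.SynthConfig(seed=21, n_trials=6, effect_size=0.0, n_cells=12)
        cm, _, _ = fc.generate_cell_session(cfg)
        c = fc.decode_cs_vs_popsize(cm, sizes=np.arange(2, 9, 2), n_reps=10,
                                    n_shuffle_reps=10, seed=3)
        chance = _expected_coinflip_f1([1, 1, 1, 1, 2])
        assert abs(c.shuffle_scores.mean() - chance) < 0.05
        assert abs(c.scores.mean() - chance) < 0.1

    def test_oversized_request_truncates_with_warning(self):
        cfg = fc.SynthConfig(seed=2, n_trials=5, n_cells=6)
        cm, _, _ = fc.generate_cell_session(cfg)
        with pytest.warns(UserWarning, match="truncat"):
            c = fc.decode_cs_vs_popsize(cm, sizes=np.arange(2, 10),
                                        n_reps=2, n_shuffle_reps=2, seed=0)
        assert c.sizes.max() == 6


class TestSaturatingFit:
    def test_noiseless_exact_recovery(self):
        n = np.arange(2, 101)
        fit = SaturatingModel(n, 0.9 * n / (3 + n)).fit(n_boot=0)
        assert abs(fit.a - 3) < 1e-4
        assert abs(fit.b - 0.9) < 1e-5
        assert fit.info_rate == pytest.approx(0.30, abs=1e-5)

    def test_flat_curve_limit(self):
        n = np.arange(2, 50)
        fit = SaturatingModel(n, np.full(n.size, 0.8)).fit(n_boot=0)
        assert fit.a < 0.1          # saturation rate collapses to the bound
        assert fit.b == pytest.approx(0.8, abs=0.01)

    def test_grid_bruteforce_oracle_agreement(self):
        """On a noiseless curve, a brute-force grid search over (a, b)
        agrees with the least-squares optimum."""
        n = np.arange(2, 101, dtype=float)
        y = 0.62 * n / (7.5 + n)
        grid_a = np.linspace(5, 10, 401)
        grid_b = np.linspace(0.4, 0.9, 401)
        sse = [(np.sum((y - _saturating(n, a, b)) ** 2), a, b)
               for a in grid_a for b in grid_b]
        _, a_star, b_star = min(sse)
        fit = SaturatingModel(n, y).fit(n_boot=0)
        assert abs(fit.a - a_star) < 2e-2   # grid resolution 0.0125
        assert abs(fit.b - b_star) < 2e-3
        assert abs(fit.a - 7.5) < 1e-4

    def test_noisy_bootstrap_recovers_info_rate(self):
        gen = np.random.default_rng(0)
        n = np.arange(2, 101)
        scores = (0.9 * n / (3 + n))[:, None] + gen.normal(0, 0.02, (n.size, 50))
        fit = SaturatingModel(n, scores).fit(n_boot=200, rng=1)
        med = fit.bootstrap_median()["info_rate"]
        assert abs(med - 0.30) / 0.30 < 0.15

    def test_results_summary_mentions_parameters(self):
        n = np.arange(2, 30)
        fit = SaturatingModel(n, 0.8 * n / (5 + n)).fit(n_boot=10, rng=0)
        text = fit.summary()
        assert "info per neuron" in text and "bootstrap" in text


class TestPcaTrajectories:
    def test_rank_one_data_has_pc1_variance_one(self, rng):
        resp = np.sin(np.linspace(0, np.pi, 40))
        mat = np.outer(rng.uniform(0.5, 2.0, 20), resp)
        tr = fc.pca_trajectories({"only": mat})
        assert tr.variance_explained["only"][0] == pytest.approx(1.0, abs=1e-8)
        assert tr.p_values is None

    def test_variance_invariant_to_neuron_permutation(self, rng):
        mat = rng.normal(size=(30, 40))
        a = fc.pca_trajectories({"g": mat})
        b = fc.pca_trajectories({"g": mat[rng.permutation(30)]})
        np.testing.assert_allclose(a.variance_explained["g"],
                                   b.variance_explained["g"], atol=1e-10)

    def test_identical_groups_not_flagged(self, rng):
        flags = []
        for s in range(6):
            gen = np.random.default_rng(s)
            a, b = gen.normal(size=(25, 30)), gen.normal(size=(25, 30))
            tr = fc.pca_trajectories({"a": a, "b": b}, n_perm=200, seed=s)
            flags.append(tr.flagged.any())
        assert sum(flags) <= 1

    def test_flat_vs_structured_group_flagged_near_onset(self, rng):
        t = np.linspace(-5, 5, 50)
        resp = np.exp(-((t - 1) / 1.5) ** 2)
        A = np.outer(rng.uniform(0.5, 1.5, 30), resp) + rng.normal(0, 0.1, (30, 50))
        B = rng.normal(0, 0.1, (30, 50))
        tr = fc.pca_trajectories({"A": A, "B": B}, n_perm=300, seed=0)
        onset_bins = (t > 0) & (t < 2.5)
        assert tr.flagged[onset_bins].all()


class TestKmeansResponses:
    def test_recovers_four_archetypes(self, rng):
        t = np.linspace(-5, 30, 70)
        shapes = [np.exp(-((t - 2) / 2) ** 2), -np.exp(-((t - 2) / 2) ** 2),
                  np.where(t > 0, 1.0, 0.0), np.zeros_like(t)]
        truth, rows = [], []
        for k, shape in enumerate(shapes):
            for _ in range(15):
                rows.append(shape + rng.normal(0, 0.05, t.size))
                truth.append(k)
        labels, centroids = fc.kmeans_responses(np.array(rows), k=4, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert centroids.shape == (4, t.size)

    def test_fewer_neurons_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            fc.kmeans_responses(np.zeros((3, 10)), k=4)

    def test_same_seed_same_labels(self, rng):
        X = rng.normal(size=(30, 20))
        a, _ = fc.kmeans_responses(X, seed=5)
        b, _ = fc.kmeans_responses(X, seed=5)
        np.testing.assert_array_equal(a, b)


class TestCoefFreezingCorrelation:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = fc.coef_freezing_correlation(x, 10 * x)
        assert r == pytest.approx(1.0)
        r2, _ = fc.coef_freezing_correlation(x, -10 * x)
        assert r2 == pytest.approx(-1.0)

    def test_hand_checked_example(self):
        # r = 55 / sqrt(5 * 650) = 0.96476
        r, p = fc.coef_freezing_correlation([1, 2, 3, 4], [10, 20, 25, 45])
        assert r == pytest.approx(55 / np.sqrt(3250), abs=1e-6)
        assert 0 < p < 0.05

    def test_mouse_averaging(self):
        coefs = [1.0, 3.0, 5.0, 7.0]       # mice 0 and 1, two neurons each
        ids = [0, 0, 1, 1]
        freezing = [2.0, 6.0, 4.0]
        with pytest.raises(ValueError):
            fc.coef_freezing_correlation(coefs, freezing, mouse_ids=ids)
        r, _ = fc.coef_freezing_correlation(coefs + [9.0, 11.0], [2.0, 6.0, 10.0],
                                            mouse_ids=ids + [2, 2])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fc.coef_freezing_correlation([1, 1, 1], [2, 3, 4])
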