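import numpy as np
import pytest
from scipy.stats import norm
from sklearn.base import clone

from gazeway.mixture import (ClusterSummary, DataSparsityError, GazeTHMixture,
                             MixtureInit, default_init_grid, em_fit, grid_fit,
                             summarise_fit, weights_along_track)


def make_two_cluster_data(rng, n=2000, mu_gf=2.0, sd_gf=0.3, c_ef=30.0,
                          sd_ef=0.2, w_ef=0.3, noise_frac=0.10,
                          x_lo=24.0, x_hi=29.0, th_max=8.0):
    """TH-space generator with exact ground truth: GF i.i.d. over x, EF on
    the th = c_ef - x diagonal, uniform noise."""
    n_noise = int(round(n * noise_frac))
    n_ef = int(round((n - n_noise) * w_ef / (1 - noise_frac) * (1 - noise_frac)))
    n_ef = int(round((n - n_noise) * w_ef))
    n_gf = n - n_noise - n_ef
    x = rng.uniform(x_lo, x_hi, n)
    th = np.empty(n)
    th[:n_gf] = rng.normal(mu_gf, sd_gf, n_gf)
    th[n_gf:n_gf + n_ef] = c_ef - x[n_gf:n_gf + n_ef] + rng.normal(0, sd_ef, n_ef)
    th[n_gf + n_ef:] = rng.uniform(0, th_max, n_noise)
    labels = np.array(["GF"] * n_gf + ["EF"] * n_ef + ["noise"] * n_noise)
    perm = rng.permutation(n)
    return np.column_stack([x, th])[perm], labels[perm]


GRID_30 = [MixtureInit(mu_gf=m, c_ef=29.0 + o)
           for m in (1.5, 2.0, 2.5) for o in (0.5, 1.0, 1.5)]


class TestEStepOracle:
    def test_responsibilities_equal_brute_force_bayes(self):
        """One E-step on a 5-point toy equals the posterior computed by
        direct density evaluation, to 1e-12."""
        X = np.array([[1.0, 2.1], [2.0, 1.4], [3.0, 27.0 - 3.0],
                      [4.0, 5.5], [5.0, 0.3]])
        mix = GazeTHMixture(init=MixtureInit(2.0, 27.0, 0.4, 0.3, (0.5, 0.3, 0.2)),
                            min_samples=1, max_iter=1)
        mix.fit(X)
        # brute force: unnormalised w_k * f_k per component
        w = np.array([0.5, 0.3, 0.2])
        f = np.column_stack([
            norm.pdf(X[:, 1], 2.0, 0.4),
            norm.pdf(X[:, 1], 27.0 - X[:, 0], 0.3),
            np.where((X[:, 1] >= 0) & (X[:, 1] <= 8.0), 1 / 8.0, 0.0),
        ])
        expected = w * f
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(mix.responsibilities_, expected, atol=1e-12)

    def test_loglik_monotone_every_iteration(self):
        rng = np.random.default_rng(0)
        X, _ = make_two_cluster_data(rng)
        fit = grid_fit(X, GRID_30)
        assert np.all(np.diff(fit.log_likelihood_path_) >= -1e-9)


class TestEmFit:
    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(42)
        X, _ = make_two_cluster_data(rng, n=2000, w_ef=0.3, noise_frac=0.10)
        fit = grid_fit(X, GRID_30)
        assert fit.mu_gf_ == pytest.approx(2.0, abs=0.05)
        assert fit.c_ef_ == pytest.approx(30.0, abs=0.05)
        # weights of emitted mixture: GF 0.6, EF 0.3, noise 0.1
        np.testing.assert_allclose(fit.weights_, [0.6, 0.3, 0.1], atol=0.03)

    def test_single_component_degenerate_case(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 1000)
        th = rng.normal(2.0, 0.3, 1000)
        fit = GazeTHMixture(bend_entry_time_s=5.0).fit(np.column_stack([x, th]))
        assert fit.weights_[1] <= 0.02
        assert fit.mu_gf_ == pytest.approx(th.mean(), abs=0.02)

    def test_refuses_sparse_data(self):
        X = np.zeros((49, 2))
        with pytest.raises(DataSparsityError):
            GazeTHMixture().fit(X)

    def test_sigma_collapse_prunes_component(self):
        rng = np.random.default_rng(2)
        # all mass exactly on one diagonal: the EF sd collapses below the
        # floor, so the cluster is pruned to weight zero and flagged
        # rather than chasing a degenerate density spike
        x = rng.uniform(24, 29, 500)
        X = np.column_stack([x, 30.0 - x])
        fit = GazeTHMixture(init=MixtureInit(2.0, 30.0), min_samples=1).fit(X)
        assert "ef" in fit.pruned_
        assert fit.weights_[1] == 0.0


class TestGridFit:
    def test_selected_fit_maximises_likelihood(self):
        rng = np.random.default_rng(3)
        X, _ = make_two_cluster_data(rng, n=800)
        fit = grid_fit(X, GRID_30)
        assert fit.log_likelihood_ >= max(fit.candidate_log_likelihoods_) - 1e-9

    def test_grid_of_one_equals_em_fit(self):
        rng = np.random.default_rng(4)
        X, _ = make_two_cluster_data(rng, n=600)
        init = MixtureInit(2.0, 30.0)
        a = em_fit(X, init)
        b = grid_fit(X, [init])
        assert a.log_likelihood_ == pytest.approx(b.log_likelihood_, abs=1e-12)
        assert a.mu_gf_ == pytest.approx(b.mu_gf_, abs=1e-12)

    def test_grid_dominates_deliberately_bad_single_init(self):
        rng = np.random.default_rng(5)
        X, _ = make_two_cluster_data(rng, n=1500)
        bad = em_fit(X, MixtureInit(mu_gf=5.0, c_ef=33.0))
        good = grid_fit(X, GRID_30)
        assert good.log_likelihood_ >= bad.log_likelihood_ - 1e-9
        assert good.mu_gf_ == pytest.approx(2.0, abs=0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_fit(np.zeros((100, 2)), [])


class TestSummarise:
    def test_pure_gf_composed_equals_gf_mean(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 500)
        th = rng.normal(2.0, 0.3, 500)
        X = np.column_stack([x, th])
        fit = GazeTHMixture(bend_entry_time_s=5.0).fit(X)
        s = summarise_fit(fit, X)
        assert s.composed_mean_th == pytest.approx(s.gf_mean_th, abs=1e-6) \
            or s.ef_weight < 0.05

    def test_hard_responsibility_hand_example(self):
        """4 points with effectively 0/1 responsibilities: the weighted
        cluster means reduce to the per-group arithmetic means."""
        X = np.array([[0.0, 2.0], [1.0, 2.2], [0.0, 30.0], [1.0, 29.2]])
        fit = GazeTHMixture(
            init=MixtureInit(2.1, 30.1, 0.2, 0.2, (0.5, 0.5, 1e-6)),
            min_samples=1, max_iter=1, th_max_s=40.0).fit(X)
        s = summarise_fit(fit, X)
        assert s.gf_mean_th == pytest.approx(np.mean([2.0, 2.2]), abs=1e-6)
        assert s.ef_mean_th == pytest.approx(np.mean([30.0, 29.2]), abs=1e-6)

    def test_composed_mean_tracks_empirical_mean(self):
        rng = np.random.default_rng(7)
        X, labels = make_two_cluster_data(rng, n=2000)
        fit = grid_fit(X, GRID_30)
        s = summarise_fit(fit, X)
        empirical = X[labels != "noise", 1].mean()
        assert s.composed_mean_th == pytest.approx(empirical, abs=0.05)
        assert isinstance(s, ClusterSummary)


class TestWeightsAlongTrack:
    def test_curves_sum_to_one(self):
        rng = np.random.default_rng(8)
        X, _ = make_two_cluster_data(rng, n=800)
        fit = grid_fit(X, GRID_30)
        _, curves = weights_along_track(fit, X, bandwidth_s=0.5)
        np.testing.assert_allclose(curves.sum(axis=1), 1.0, atol=1e-6)

    def test_infinite_bandwidth_gives_flat_global_weights(self):
        rng = np.random.default_rng(9)
        X, _ = make_two_cluster_data(rng, n=800)
        fit = grid_fit(X, GRID_30)
        resp = fit.predict_proba(X)
        _, curves = weights_along_track(fit, X, bandwidth_s=1e9)
        np.testing.assert_allclose(
            curves, np.tile(resp.mean(axis=0), (len(curves), 1)), atol=1e-6)

    def test_ef_weight_peaks_in_its_scheduled_window(self):
        """EF episodes only during part of the trial: the smoothed EF
        weight curve peaks inside that window and decays outside it."""
        rng = np.random.default_rng(10)
        x_gf = rng.uniform(24.0, 29.0, 1200)
        th_gf = rng.normal(2.0, 0.3, 1200)
        x_ef = rng.uniform(25.0, 26.5, 600)      # approach window only
        th_ef = 30.0 - x_ef + rng.normal(0, 0.2, 600)
        X = np.column_stack([np.concatenate([x_gf, x_ef]),
                             np.concatenate([th_gf, th_ef])])
        fit = grid_fit(X, GRID_30)
        times, curves = weights_along_track(fit, X, bandwidth_s=0.3)
        peak_t = times[np.argmax(curves[:, 1])]
        assert 25.0 <= peak_t <= 26.5
        edge = curves[(times < 24.5) | (times > 28.0), 1]
        assert edge.max() < curves[:, 1].max() - 0.2


class TestRecoveryProperties:
    def test_bias_and_rmse_over_seeds(self):
        """Parameter recovery across 20 generator seeds: bias < 0.02 s,
        RMSE < 0.06 s for both intercepts."""
        mus, cs = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, _ = make_two_cluster_data(rng, n=1500)
            fit = grid_fit(X, GRID_30)
            mus.append(fit.mu_gf_)
            cs.append(fit.c_ef_)
        mus, cs = np.asarray(mus), np.asarray(cs)
        assert abs(mus.mean() - 2.0) < 0.02
        assert abs(cs.mean() - 30.0) < 0.02
        assert np.sqrt(np.mean((mus - 2.0) ** 2)) < 0.06
        assert np.sqrt(np.mean((cs - 30.0) ** 2)) < 0.06

    def test_detects_condition_shift(self):
        """Two synthetic conditions 0.2 s apart in GF mean: the fitted
        difference recovers 0.20 +- 0.05."""
        rng = np.random.default_rng(11)
        Xa, _ = make_two_cluster_data(rng, n=1500, mu_gf=2.0)
        Xb, _ = make_two_cluster_data(rng, n=1500, mu_gf=2.2)
        fa, fb = grid_fit(Xa, GRID_30), grid_fit(Xb, GRID_30)
        assert fb.mu_gf_ - fa.mu_gf_ == pytest.approx(0.20, abs=0.05)


class TestSklearnApi:
    def test_clone_and_params_round_trip(self):
        mix = GazeTHMixture(bend_entry_time_s=7.0, tol=1e-8)
        c = clone(mix)
        assert c.get_params()["bend_entry_time_s"] == 7.0
        c.set_params(tol=1e-5)
        assert c.tol == 1e-5

    def test_predict_proba_rows_normalised(self):
        rng = np.random.default_rng(12)
        X, _ = make_two_cluster_data(rng, n=500)
        fit = grid_fit(X, GRID_30)
        p = fit.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(fit.score(X))

    def test_default_grid_spans_reported_ranges(self):
        grid = default_init_grid(5.0)
        assert len(grid) == 9
        assert {g.mu_gf for g in grid} == {1.5, 2.0, 2.5}
        assert {round(g.c_ef - 5.0, 3) for g in grid} == {0.5, 1.0, 1.5}
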