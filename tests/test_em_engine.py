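import warnings

import numpy as np
import pytest

from roughseg import em_engine as em
from roughseg import synthetic as syn
from roughseg.bounded_model import MCSampleSet, Posteriors
from roughseg.grid import ImageGrid
from roughseg.metrics import ccr
from roughseg.rough_regions import BO, NE, PO, RoughPartition, ThresholdPair


def make_partition(region):
    region = np.asarray(region, dtype=np.int8)
    ind = np.where(region == PO, 1.0, np.where(region == NE, 0.0, 0.5))
    return RoughPartition(region=region, distance=np.zeros_like(ind),
                         indicator=ind, thresholds=ThresholdPair(0.1, 0.2))


class TestInitKMeans:
    def test_two_value_image_recovers_values(self):
        base = np.zeros((8, 8))
        base[:, 4:] = 1.0
        params = em.init_kmeans(ImageGrid(base), K=2, L=1, seed=0)
        np.testing.assert_allclose(np.sort(params.mu.ravel()), [0.0, 1.0],
                                   atol=1e-12)

    def test_single_component_equals_centroid(self, rng):
        vals = np.concatenate([rng.normal(0.2, 0.02, 32),
                               rng.normal(0.8, 0.02, 32)])
        img = ImageGrid(vals.reshape(8, 8))
        params = em.init_kmeans(img, K=2, L=1, seed=0)
        mus = np.sort(params.mu.ravel())
        assert abs(mus[0] - vals[vals < 0.5].mean()) < 0.01
        assert abs(mus[1] - vals[vals >= 0.5].mean()) < 0.01

    def test_noisy_two_class_centroids_near_truth(self, rng):
        vals = np.where(rng.random(4096) < 0.5, 0.25, 0.75) \
            + rng.normal(0, 0.05, 4096)
        params = em.init_kmeans(ImageGrid(vals.reshape(64, 64)), 2, 3, seed=1)
        cm = np.sort(params.cluster_means().ravel())
        np.testing.assert_allclose(cm, [0.25, 0.75], atol=0.05)

    def test_uniform_priors_and_shapes(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (10, 10)))
        params = em.init_kmeans(img, K=3, L=2, seed=0)
        np.testing.assert_allclose(params.pi, 1 / 3)
        np.testing.assert_allclose(params.eta, 1 / 2)
        assert params.mu.shape == (3, 2, 1)
        # covariances SPD
        assert np.all(np.linalg.eigvalsh(params.sigma) > 0)

    def test_deterministic_given_seed(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (12, 12)))
        a = em.init_kmeans(img, 3, 2, seed=5)
        b = em.init_kmeans(img, 3, 2, seed=5)
        np.testing.assert_array_equal(a.mu, b.mu)


class TestRoughOverrides:
    def test_case_analysis(self):
        region = np.array([[[PO, NE, BO]]])  # one pixel, K = 3
        post = Posteriors(z=np.array([[0.2, 0.5, 0.3]]),
                          y=np.array([[[0.6, 0.4]]] * 1).repeat(3, axis=1))
        got = em.apply_rough_overrides(post, make_partition(region))
        np.testing.assert_allclose(got.z_tilde, [[1.0, 0.0, 0.3]])
        np.testing.assert_allclose(got.y_tilde[0, 0], [1.0, 1.0])
        np.testing.assert_allclose(got.y_tilde[0, 1], [0.0, 0.0])
        np.testing.assert_allclose(got.y_tilde[0, 2], post.y[0, 2])

    def test_all_boundary_keeps_soft(self, rng):
        z = rng.dirichlet(np.ones(2), size=4)
        y = rng.dirichlet(np.ones(2), size=(4, 2))
        region = np.full((2, 2, 2), BO)
        got = em.apply_rough_overrides(Posteriors(z=z, y=y),
                                       make_partition(region))
        np.testing.assert_array_equal(got.z_tilde, z)
        np.testing.assert_array_equal(got.y_tilde, y)

    def test_orphan_pixel_keeps_soft_with_warning(self, rng):
        z = rng.dirichlet(np.ones(2), size=1)
        y = rng.dirichlet(np.ones(2), size=(1, 2))
        region = np.full((1, 1, 2), NE)
        with pytest.warns(UserWarning, match="negative region of"):
            got = em.apply_rough_overrides(Posteriors(z=z, y=y),
                                           make_partition(region))
        np.testing.assert_array_equal(got.z_tilde, z)


class TestMeanUpdate:
    def test_degenerate_samples_give_weighted_mean(self, rng):
        # samples pinned at the old mean: the correction vanishes exactly
        x = rng.uniform(0, 1, (6, 1))
        zt = rng.uniform(0.1, 1, (6, 1))
        yt = np.ones((6, 1, 1))
        mu_old = np.array([[[0.4]]])
        samples = MCSampleSet(np.full((1, 1, 50, 1), 0.4), np.ones((1, 1, 50)))
        got = em.update_means(x, zt, yt, samples, mu_old)
        expected = (zt[:, 0] * x[:, 0]).sum() / zt.sum()
        assert got[0, 0, 0] == pytest.approx(expected)

    def test_single_pixel_weight(self):
        x = np.array([[0.1], [0.9]])
        zt = np.array([[0.0], [1.0]])
        yt = np.ones((2, 1, 1))
        samples = MCSampleSet(np.full((1, 1, 10, 1), 0.5), np.ones((1, 1, 10)))
        got = em.update_means(x, zt, yt, samples, np.array([[[0.5]]]))
        assert got[0, 0, 0] == pytest.approx(0.9)

    def test_unit_indicator_correction_shrinks_with_m(self, rng):
        x = rng.uniform(0, 1, (20, 1))
        zt = np.ones((20, 1))
        yt = np.ones((20, 1, 1))
        mu_old = np.array([[[0.5]]])
        s = rng.normal(0.5, 0.1, (1, 1, 200_000, 1))
        got = em.update_means(x, zt, yt, MCSampleSet(s, np.ones(s.shape[:3])),
                              mu_old)
        assert got[0, 0, 0] == pytest.approx(x.mean(), abs=2e-3)

    def test_matches_hand_evaluation(self, rng):
        N, K, L = 5, 2, 2
        x = rng.uniform(0, 1, (N, 1))
        zt = rng.uniform(0, 1, (N, K))
        yt = rng.uniform(0, 1, (N, K, L))
        mu_old = rng.uniform(0, 1, (K, L, 1))
        s = rng.normal(0.5, 0.2, (K, L, 30, 1))
        h = rng.uniform(0.1, 1.0, (K, L, 30))
        got = em.update_means(x, zt, yt, MCSampleSet(s, h), mu_old)
        for k in range(K):
            for l in range(L):
                w = zt[:, k] * yt[:, k, l]
                data = (w[:, None] * x).sum(0) / w.sum()
                corr = ((mu_old[k, l] - s[k, l]) * h[k, l][:, None]).sum(0) \
                    / h[k, l].sum()
                np.testing.assert_allclose(got[k, l], data - corr, rtol=1e-10)

    def test_vanishing_mass_keeps_previous(self, rng):
        x = rng.uniform(0, 1, (4, 1))
        zt = np.zeros((4, 1))
        yt = np.ones((4, 1, 1))
        mu_old = np.array([[[0.37]]])
        s = rng.normal(0.4, 0.1, (1, 1, 20, 1))
        with pytest.warns(UserWarning, match="vanishing"):
            got = em.update_means(x, zt, yt, MCSampleSet(s, np.ones((1, 1, 20))),
                                  mu_old)
        assert got[0, 0, 0] == 0.37


class TestCovarianceUpdate:
    def test_unit_indicator_recovers_weighted_scatter(self, rng):
        N = 400
        x = rng.normal(0.5, 0.1, (N, 1))
        zt = np.ones((N, 1))
        yt = np.ones((N, 1, 1))
        mu = np.array([[[x.mean()]]])
        sig_old = np.array([[[[0.01]]]])
        s = rng.normal(0.5, 0.1, (1, 1, 300_000, 1))
        got = em.update_covariances(x, zt, yt, mu, mu, sig_old,
                                    MCSampleSet(s, np.ones(s.shape[:3])),
                                    reg=1e-9)
        scatter = ((x - x.mean()) ** 2).mean()
        assert got[0, 0, 0, 0] == pytest.approx(scatter, rel=0.05)

    def test_single_pixel_weight_is_floored_spd(self, rng):
        x = np.array([[0.2], [0.8]])
        zt = np.array([[0.0], [1.0]])
        yt = np.ones((2, 1, 1))
        mu = np.array([[[0.8]]])
        s = np.full((1, 1, 20, 1), 0.8)
        got = em.update_covariances(x, zt, yt, mu, mu, np.array([[[[0.0]]]]),
                                    MCSampleSet(s, np.ones((1, 1, 20))),
                                    reg=1e-6)
        assert got[0, 0, 0, 0] >= 1e-6

    def test_matches_hand_evaluation(self, rng):
        N, K, L = 6, 2, 1
        x = rng.uniform(0, 1, (N, 1))
        zt = rng.uniform(0.2, 1, (N, K))
        yt = np.ones((N, K, L))
        mu_new = rng.uniform(0, 1, (K, L, 1))
        mu_old = rng.uniform(0, 1, (K, L, 1))
        sig_old = np.full((K, L, 1, 1), 0.04)
        # samples centred on mu_old so the correction stays small and the
        # eigenvalue clip never engages
        s = mu_old[:, :, None, :] + rng.normal(0, 0.2, (K, L, 40, 1))
        h = rng.uniform(0.3, 1.0, (K, L, 40))
        got = em.update_covariances(x, zt, yt, mu_new, mu_old, sig_old,
                                    MCSampleSet(s, h), reg=1e-12)
        for k in range(K):
            w = zt[:, k] * yt[:, k, 0]
            scatter = (w * (x[:, 0] - mu_new[k, 0, 0]) ** 2).sum() / w.sum()
            corr = (h[k, 0] * ((s[k, 0, :, 0] - mu_old[k, 0, 0]) ** 2
                               - sig_old[k, 0, 0, 0])).sum() / h[k, 0].sum()
            np.testing.assert_allclose(got[k, 0, 0, 0],
                                       scatter - corr + 1e-12, rtol=1e-8)


class TestPriorUpdate:
    def test_zero_responsibility_row_returns_e(self, rng):
        E = rng.dirichlet(np.ones(3), size=4)
        F = rng.dirichlet(np.ones(2), size=(4, 3))
        pi, eta = em.update_priors(np.zeros((4, 3)), np.zeros((4, 3, 2)), E, F)
        np.testing.assert_allclose(pi, E)
        np.testing.assert_allclose(eta, F)

    def test_hard_assignment_with_uniform_e(self):
        K = 4
        zt = np.zeros((1, K))
        zt[0, 2] = 1.0
        E = np.full((1, K), 1 / K)
        pi, _ = em.update_priors(zt, np.zeros((1, K, 1)), E,
                                 np.ones((1, K, 1)))
        assert pi[0, 2] == pytest.approx((1 + 1 / K) / 2)

    def test_matches_naive_loop(self, rng):
        N, K, L = 5, 3, 2
        zt = rng.uniform(0, 1, (N, K))
        yt = rng.uniform(0, 1, (N, K, L))
        E = rng.dirichlet(np.ones(K), size=N)
        F = rng.dirichlet(np.ones(L), size=(N, K))
        pi, eta = em.update_priors(zt, yt, E, F)
        for i in range(N):
            np.testing.assert_allclose(
                pi[i], (zt[i] + E[i]) / (zt[i] + E[i]).sum(), rtol=1e-12)
            for k in range(K):
                np.testing.assert_allclose(
                    eta[i, k], (yt[i, k] + F[i, k]) / (yt[i, k] + F[i, k]).sum(),
                    rtol=1e-12)


class TestFit:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            em.FitConfig(n_clusters=1)
        with pytest.raises(ValueError):
            em.FitConfig(n_clusters=2, tol=0.0)

    def test_noiseless_two_label_phantom_is_perfect(self):
        spec = syn.PhantomSpec(size=(24, 24), luminances=(0.0, 1.0),
                               layout="stripes")
        img, gt = syn.make_phantom(spec)
        cfg = em.FitConfig(2, 1, mc_samples=500, max_iter=10, seed=0)
        res = em.fit(img, cfg)
        assert ccr(res.labels, gt) == 1.0

    def test_infinite_tolerance_stops_after_one_iteration(self):
        img, _ = syn.make_phantom(syn.PhantomSpec(size=(16, 16),
                                                  layout="stripes",
                                                  luminances=(0.0, 0.5, 1.0)))
        cfg = em.FitConfig(2, 1, mc_samples=200, max_iter=10, tol=np.inf, seed=0)
        res = em.fit(img, cfg)
        assert res.n_iter == 1 and res.converged

    def test_identical_seeds_identical_labels(self):
        spec = syn.PhantomSpec(size=(24, 24))
        img, _ = syn.make_phantom(spec)
        noisy = syn.add_gaussian_noise(img, 0, 0.01, seed=4, clip=True)
        cfg = em.FitConfig(4, 2, mc_samples=1000, max_iter=5, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = em.fit(noisy, cfg)
            b = em.fit(noisy, cfg)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.objective_trace == b.objective_trace

    def test_invariants_after_fit(self):
        spec = syn.PhantomSpec(size=(24, 24))
        img, _ = syn.make_phantom(spec)
        noisy = syn.add_gaussian_noise(img, 0, 0.02, seed=2, clip=True)
        cfg = em.FitConfig(4, 2, mc_samples=1000, max_iter=6, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = em.fit(noisy, cfg)
        p = res.params
        np.testing.assert_allclose(p.pi.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(p.eta.sum(axis=2), 1.0, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(p.sigma) > 0)
        assert np.all((res.labels >= 1) & (res.labels <= 4))
        assert res.n_iter <= 6
        assert len(res.objective_trace) == res.n_iter

    def test_mean_recovery_on_coherent_two_region_image(self):
        # two tissue-like regions at 0.25 / 0.75 with sigma = 0.05
        spec = syn.PhantomSpec(size=(64, 64), luminances=(0.25, 0.75),
                               layout="stripes", seed=0)
        img, _ = syn.make_phantom(spec)
        noisy = syn.add_gaussian_noise(img, 0, 0.05**2, seed=0)
        cfg = em.FitConfig(2, 1, mc_samples=2000, max_iter=20, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = em.fit(noisy, cfg)
        mus = np.sort(res.params.cluster_means().ravel())
        np.testing.assert_allclose(mus, [0.25, 0.75], atol=0.02)
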