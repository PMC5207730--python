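"""EM fitting loop for the rough-set bounded asymmetric mixture.

One iteration runs, in order: (1) rough regions from the current cluster
means; (2) E-step — Monte-Carlo normalizers, soft responsibilities, and
the rough-region overrides (Po pixels pinned to 1, Ne pixels to 0);
(3) M-step — directional prior factors E/F, then means, covariances and
the per-pixel priors pi/eta. Convergence is declared when the total
shift of the component means between successive iterations drops below
``tol``.

The mean and covariance updates carry Monte-Carlo bias-correction terms
that account for the truncation of each component to its bounded
support; both are single fixed-point updates evaluated at the
previous-iteration parameters, using the same sample set as the
normalizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import spatial_priors
from .bounded_model import (
    MCSampleSet,
    MixtureParams,
    Posteriors,
    draw_samples,
    mc_normalizer,
    objective,
    posteriors,
)
from .grid import ImageGrid
from .rough_regions import (
    BO,
    NE,
    PO,
    RoughPartition,
    ThresholdPair,
    assign_rough_regions,
    bounded_indicator,
    compute_thresholds,
)

#: relative covariance regularization (times squared intensity range)
COV_REG = 1e-6
#: responsibility mass below which a component update is skipped
MASS_FLOOR = 1e-10


@dataclass
class FitConfig:
    """Settings for one segmentation run.

    n_clusters : K, number of image classes (>= 2)
    n_components : L, truncated Gaussians per class
    mc_samples : M, Monte-Carlo draws per (k, l) per iteration
    tol : threshold on the summed mean shift between iterations
    recompute_regions : refresh the rough regions from the current means
        every iteration (the printed loop); False freezes them at init
    freeze_samples : reuse one sample seed across iterations, which makes
        the objective exactly monotone (fresh draws are monotone only up
        to MC noise)
    unbounded : force H = 1 everywhere (no truncation, no overrides);
        the model then reduces to a spatially-weighted Gaussian mixture
    """

    n_clusters: int
    n_components: int = 3
    mc_samples: int = 1_000_000
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0
    recompute_regions: bool = True
    freeze_samples: bool = False
    unbounded: bool = False

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.n_components < 1 or self.mc_samples < 1:
            raise ValueError("n_components and mc_samples must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class SegmentationResult:
    """Output of :func:`fit`."""

    labels: np.ndarray  # (H, W), values 1..K
    posteriors: np.ndarray  # final z-tilde, (N, K)
    params: MixtureParams
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    thresholds: ThresholdPair | None = None


def init_kmeans(image: ImageGrid, K: int, L: int, seed: int = 0) -> MixtureParams:
    """K-means initialization of all mixture parameters.

    Top-level k-means on pixel intensities gives the cluster structure
    (clusters sorted by mean intensity so labelling is reproducible);
    a nested k-means with L centers inside each cluster seeds the
    component means, with covariances from the within-component scatter.
    Priors start uniform: pi = 1/K, eta = 1/L.
    """
    x = image.pixels()
    N, D = x.shape
    rs = int(seed) % (2**31)
    km = KMeans(n_clusters=K, n_init=10, random_state=rs).fit(x)
    order = np.argsort(km.cluster_centers_.mean(axis=1))
    centers = km.cluster_centers_[order]
    labels = np.argsort(order)[km.labels_]

    reg = COV_REG * max(image.intensity_range, 1e-12) ** 2
    mu = np.empty((K, L, D))
    sigma = np.empty((K, L, D, D))
    rng = np.random.default_rng(rs)
    for k in range(K):
        pts = x[labels == k]
        if pts.shape[0] == 0:  # re-seed from the farthest point overall
            far = np.argmax(np.sum((x - centers[k]) ** 2, axis=1))
            pts = x[far][None, :]
        if L == 1:
            mu[k, 0] = pts.mean(axis=0)
            sub = np.zeros(pts.shape[0], dtype=int)
        elif np.unique(pts, axis=0).shape[0] < L:
            # not enough distinct points: jitter the centroid
            mu[k] = pts.mean(axis=0) + 1e-3 * image.intensity_range * \
                rng.standard_normal((L, D))
            sub = np.zeros(pts.shape[0], dtype=int)
        else:
            sub_km = KMeans(n_clusters=L, n_init=5, random_state=rs).fit(pts)
            sub_order = np.argsort(sub_km.cluster_centers_.mean(axis=1))
            mu[k] = sub_km.cluster_centers_[sub_order]
            sub = np.argsort(sub_order)[sub_km.labels_]
        for l in range(L):
            member = pts[sub == l] if L > 1 else pts
            if member.shape[0] > 1:
                sigma[k, l] = np.cov(member, rowvar=False).reshape(D, D)
            else:
                sigma[k, l] = 0.0
            sigma[k, l] += reg * np.eye(D)

    return MixtureParams(
        pi=np.full((N, K), 1.0 / K),
        eta=np.full((N, K, L), 1.0 / L),
        mu=mu,
        sigma=sigma,
        normalizer=np.ones((K, L)),
    )


def apply_rough_overrides(post: Posteriors, rough: RoughPartition) -> Posteriors:
    """Pin responsibilities by rough region: Po -> 1, Bo -> soft, Ne -> 0.

    Rows are deliberately left unnormalized — the pi/eta updates divide
    by their own row sums. A pixel falling in Ne of every cluster keeps
    its soft responsibilities (an all-zero row would drop the pixel from
    every update).
    """
    region = rough.region.reshape(post.z.shape)
    zt = np.where(region == PO, 1.0, np.where(region == NE, 0.0, post.z))
    yt = np.where(region[:, :, None] == PO, 1.0,
                  np.where(region[:, :, None] == NE, 0.0, post.y))
    orphan = np.all(region == NE, axis=1)
    if np.any(orphan):
        warnings.warn(f"{int(orphan.sum())} pixel(s) in the negative region of "
                      "every cluster; keeping soft responsibilities")
        zt[orphan] = post.z[orphan]
        yt[orphan] = post.y[orphan]
    return Posteriors(z=post.z, y=post.y, z_tilde=zt, y_tilde=yt)


def _correction_weights(samples: MCSampleSet) -> np.ndarray:
    """Per-(k, l) indicator sums, floored so they can divide."""
    return np.maximum(samples.indicator.sum(axis=2), MASS_FLOOR)


def update_means(x: np.ndarray, z_tilde: np.ndarray, y_tilde: np.ndarray,
                 samples: MCSampleSet, mu_old: np.ndarray) -> np.ndarray:
    """Weighted data mean minus the Monte-Carlo truncation correction.

    mu_kl = sum_i w_ikl x_i / sum_i w_ikl
            - sum_m (mu_old - s_mkl) H(s_mkl) / sum_m H(s_mkl)
    with w = z-tilde * y-tilde. Components with vanishing responsibility
    mass keep their previous mean.
    """
    w = z_tilde[:, :, None] * y_tilde  # (N, K, L)
    mass = w.sum(axis=0)  # (K, L)
    data_mean = np.einsum("ikl,id->kld", w, x)
    hsum = _correction_weights(samples)
    sample_mean = np.einsum("klm,klmd->kld", samples.indicator, samples.samples) \
        / hsum[:, :, None]
    correction = mu_old - sample_mean
    mu_new = mu_old.copy()
    ok = mass > MASS_FLOOR
    if not np.all(ok):
        warnings.warn("component(s) with vanishing responsibility mass; "
                      "keeping previous means")
    mu_new[ok] = data_mean[ok] / mass[ok][:, None] - correction[ok]
    return mu_new


def update_covariances(x: np.ndarray, z_tilde: np.ndarray, y_tilde: np.ndarray,
                       mu_new: np.ndarray, mu_old: np.ndarray,
                       sigma_old: np.ndarray, samples: MCSampleSet,
                       reg: float, cap: float = np.inf) -> np.ndarray:
    """Weighted scatter minus the MC correction, then forced SPD.

    The correction bracket ((s - mu)(s - mu)^T - Sigma) is evaluated at
    the previous-iteration parameters that generated the samples; the
    data scatter uses the freshly updated means.

    Eigenvalues are clipped into [reg, cap]. The cap is the squared
    support radius: the truncation correction inflates the covariance to
    explain bounded data with an unbounded Gaussian, and once the
    standard deviation passes the support radius the truncated density
    is insensitive to further growth, so the fixed-point update can
    diverge; clipping there changes nothing the model can express.
    """
    K, L, D = mu_new.shape
    w = z_tilde[:, :, None] * y_tilde
    mass = w.sum(axis=0)
    hsum = _correction_weights(samples)
    sigma_new = sigma_old.copy()
    for k in range(K):
        for l in range(L):
            if mass[k, l] <= MASS_FLOOR:
                continue
            diff = x - mu_new[k, l]
            scatter = np.einsum("i,id,ie->de", w[:, k, l], diff, diff) / mass[k, l]
            sdiff = samples.samples[k, l] - mu_old[k, l]
            samp_scatter = np.einsum(
                "m,md,me->de", samples.indicator[k, l], sdiff, sdiff
            ) / hsum[k, l]
            h_frac = samples.indicator[k, l].sum() / hsum[k, l]
            correction = samp_scatter - h_frac * sigma_old[k, l]
            sig = scatter - correction
            sig = 0.5 * (sig + sig.T) + reg * np.eye(D)
            vals = np.linalg.eigvalsh(sig)
            if vals[0] <= 0 or vals[-1] > cap:
                evals, evecs = np.linalg.eigh(sig)
                evals = np.clip(evals, reg, cap)
                sig = (evecs * evals) @ evecs.T
            sigma_new[k, l] = sig
    return sigma_new


def update_priors(z_tilde: np.ndarray, y_tilde: np.ndarray,
                  E: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pi = (z-tilde + E) / row sum;  eta = (y-tilde + F) / row sum."""
    pi = z_tilde + E
    pi /= pi.sum(axis=1, keepdims=True)
    eta = y_tilde + F
    eta /= eta.sum(axis=2, keepdims=True)
    return pi, eta


def _sample_indicators(samples: np.ndarray, cluster_means: np.ndarray,
                       thresholds: ThresholdPair, scale: float) -> np.ndarray:
    """H on MC samples via the neighborhood-free (n = 1) distance."""
    d = np.sum((samples - cluster_means[:, None, None, :]) ** 2, axis=3) / scale
    return np.asarray(bounded_indicator(d, thresholds))


def _unbounded_partition(image: ImageGrid, K: int,
                         thresholds: ThresholdPair) -> RoughPartition:
    shape = (image.height, image.width, K)
    return RoughPartition(
        region=np.full(shape, BO, dtype=np.int8),
        distance=np.zeros(shape),
        indicator=np.ones(shape),
        thresholds=thresholds,
    )


def fit(image: ImageGrid, config: FitConfig) -> SegmentationResult:
    """Run the full segmentation EM on one image.

    Deterministic for a fixed config: the k-means seed and every
    per-iteration Monte-Carlo draw derive from ``config.seed``. Labels
    are the argmax of the rough-overridden cluster responsibilities
    (ties to the lowest cluster index), reported in 1..K.
    """
    K, L = config.n_clusters, config.n_components
    x = image.pixels()
    scale = image.intensity_range
    thresholds = compute_thresholds(image)
    params = init_kmeans(image, K, L, config.seed)
    reg = COV_REG * max(scale, 1e-12) ** 2

    children = np.random.SeedSequence(config.seed).spawn(config.max_iter + 1)
    trace: list[float] = []
    zt = np.full((x.shape[0], K), 1.0 / K)
    rough = None
    converged = False
    n_iter = 0

    for t in range(config.max_iter):
        cluster_means = params.cluster_means()
        if config.unbounded:
            rough = _unbounded_partition(image, K, thresholds)
        elif rough is None or config.recompute_regions:
            rough = assign_rough_regions(image, cluster_means, thresholds)
        ind_flat = rough.indicator.reshape(-1, K)

        # fresh Gaussian samples from the current component parameters
        rng = np.random.default_rng(children[0] if config.freeze_samples
                                    else children[t])
        s = draw_samples(params.mu, params.sigma, config.mc_samples, rng)
        if config.unbounded:
            s_ind = np.ones(s.shape[:3])
        else:
            s_ind = _sample_indicators(s, cluster_means, thresholds, scale)
        samples = MCSampleSet(samples=s, indicator=s_ind)
        params.normalizer = np.array(
            [[mc_normalizer(s_ind[k, l]) for l in range(L)] for k in range(K)]
        )

        post = posteriors(x, params, ind_flat)
        if config.unbounded:
            post = Posteriors(z=post.z, y=post.y, z_tilde=post.z, y_tilde=post.y)
        else:
            post = apply_rough_overrides(post, rough)
        zt, yt = post.z_tilde, post.y_tilde

        E, _ = spatial_priors.prior_factor_between(post.z, params.pi, image,
                                                   cluster_means)
        F = spatial_priors.prior_factor_within(post.y, params.eta, image,
                                               params.mu)
        trace.append(objective(x, params, ind_flat, E, F))

        # squared support radius: H vanishes at distance t2 from the
        # cluster mean, i.e. at ||x - mu_k||^2 = t2 * scale
        cap = thresholds.t2 * scale if not config.unbounded else np.inf
        mu_new = update_means(x, zt, yt, samples, params.mu)
        sigma_new = update_covariances(x, zt, yt, mu_new, params.mu,
                                       params.sigma, samples, reg, cap)
        pi_new, eta_new = update_priors(zt, yt, E, F)

        shift = float(np.sum(np.linalg.norm(mu_new - params.mu, axis=2)))
        params = MixtureParams(pi=pi_new, eta=eta_new, mu=mu_new,
                               sigma=sigma_new, normalizer=params.normalizer)
        n_iter = t + 1
        if shift < config.tol:
            converged = True
            break

    labels = (np.argmax(zt, axis=1) + 1).reshape(image.height, image.width)
    return SegmentationResult(
        labels=labels, posteriors=zt, params=params, objective_trace=trace,
        n_iter=n_iter, converged=converged, thresholds=thresholds,
    )
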