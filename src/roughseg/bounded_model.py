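"""Bounded asymmetric Gaussian components, MC normalizers and posteriors.

Each cluster k is modelled as a mixture of L Gaussians truncated to the
cluster's rough bounded support: the component density is

    p(x_i | k) = sum_l eta_ikl  Phi(x_i | mu_kl, Sigma_kl) H(x_i | k) / C_kl

where H is the graded rough-set indicator and C_kl is the share of the
Gaussian mass that falls inside the support,

    C_kl = integral Phi(x | mu_kl, Sigma_kl) H(x | k) dx
         ~ (1/M) sum_m H(s_mkl),   s_mkl ~ Phi(. | mu_kl, Sigma_kl),

estimated by Monte Carlo. The same sample set feeds the bias-correction
terms of the M-step, so it is drawn once per EM iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

#: floor for the MC normalizer before it is used as a divisor
NORMALIZER_FLOOR = 1e-8
#: floor inside logs so a zero indicator/density never produces -inf * 0
DENSITY_FLOOR = 1e-300

_LOG_FLOOR = np.log(DENSITY_FLOOR)


@dataclass
class MixtureParams:
    """All free parameters of the K-cluster, L-component bounded mixture.

    pi : (N, K) per-pixel cluster priors, rows sum to 1
    eta : (N, K, L) per-pixel component weights, sum to 1 over l
    mu : (K, L, D) component means
    sigma : (K, L, D, D) component covariances (SPD)
    normalizer : (K, L) MC estimates of the truncation constants C_kl
    """

    pi: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    normalizer: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[0]

    @property
    def n_components(self) -> int:
        return self.mu.shape[1]

    @property
    def n_channels(self) -> int:
        return self.mu.shape[2]

    def cluster_means(self) -> np.ndarray:
        """Cluster-level means mu_k = sum_l w_kl mu_kl, (K, D).

        The rough regions, the directional selection and the MC-sample
        indicator are all defined against a single mean per cluster; the
        model itself only carries component means, so the cluster mean is
        the image-averaged eta-weighted combination of them.
        """
        w = self.eta.mean(axis=0)  # (K, L)
        w = w / w.sum(axis=1, keepdims=True)
        return np.einsum("kl,kld->kd", w, self.mu)

    def copy(self) -> "MixtureParams":
        return replace(
            self,
            pi=self.pi.copy(), eta=self.eta.copy(), mu=self.mu.copy(),
            sigma=self.sigma.copy(), normalizer=self.normalizer.copy(),
        )


@dataclass
class Posteriors:
    """Soft responsibilities and their rough-region overridden versions."""

    z: np.ndarray  # (N, K)
    y: np.ndarray  # (N, K, L)
    z_tilde: np.ndarray | None = None
    y_tilde: np.ndarray | None = None


@dataclass
class MCSampleSet:
    """Gaussian samples s_mkl and their indicator values, one draw per EM pass."""

    samples: np.ndarray  # (K, L, M, D)
    indicator: np.ndarray  # (K, L, M)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]


def _chol_terms(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factors and log-determinants for a (K, L, D, D) stack."""
    chol = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=-2, axis2=-1)), axis=-1)
    return chol, logdet


def log_gaussian(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log multivariate-normal density for every (pixel, k, l) triple.

    x: (N, D); mu: (K, L, D); sigma: (K, L, D, D) -> (N, K, L).
    """
    K, L, D = mu.shape
    chol, logdet = _chol_terms(sigma)
    out = np.empty((x.shape[0], K, L))
    const = D * np.log(2.0 * np.pi)
    for k in range(K):
        for l in range(L):
            diff = x - mu[k, l]
            sol = np.linalg.solve(chol[k, l], diff.T)  # (D, N)
            maha = np.sum(sol * sol, axis=0)
            out[:, k, l] = -0.5 * (maha + logdet[k, l] + const)
    return out


def gaussian_pdf(x, mean, cov) -> float:
    """Multivariate normal density at a single point (computed in log space)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    logp = log_gaussian(x[None, :], mean[None, None, :], cov[None, None, :, :])
    return float(np.exp(logp[0, 0, 0]))


def mc_normalizer(indicator_values: np.ndarray) -> float:
    """Truncation constant (1/M) sum_m H(s_m), floored before division.

    A vanished support (all indicators zero) is floored and reported,
    because the normalizer divides the component density.
    """
    vals = np.asarray(indicator_values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one MC sample")
    est = float(vals.mean())
    if est < NORMALIZER_FLOOR:
        warnings.warn("MC normalizer underflow: component support vanished; "
                      "floored at %.0e" % NORMALIZER_FLOOR)
        return NORMALIZER_FLOOR
    return est


def draw_samples(mu: np.ndarray, sigma: np.ndarray, M: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw M Gaussian vectors per (k, l): returns (K, L, M, D)."""
    K, L, D = mu.shape
    chol, _ = _chol_terms(sigma)
    eps = rng.standard_normal((K, L, M, D))
    return mu[:, :, None, :] + np.einsum("klde,klme->klmd", chol, eps)


def bounded_pdf(x, mean, cov, indicator_value: float, normalizer: float) -> float:
    """Truncated-Gaussian density Phi(x) H(x) / C at a single point."""
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    if indicator_value == 0.0:
        return 0.0
    return gaussian_pdf(x, mean, cov) * indicator_value / normalizer


def log_bounded(x: np.ndarray, params: MixtureParams,
                indicator: np.ndarray) -> np.ndarray:
    """log Psi(x_i | mu_kl, Sigma_kl) for all pixels: (N, K, L).

    ``indicator`` is the per-pixel per-cluster H, shape (N, K); zeros map
    to the density floor so downstream log-sum-exp stays finite.
    """
    logphi = log_gaussian(x, params.mu, params.sigma)
    logh = np.log(np.maximum(indicator, DENSITY_FLOOR))[:, :, None]
    return np.maximum(logphi + logh - np.log(params.normalizer)[None, :, :],
                      _LOG_FLOOR)


def component_density(x, cluster: int, params: MixtureParams,
                      indicator: np.ndarray) -> np.ndarray:
    """p(x_i | cluster) = sum_l eta_ikl Psi_kl(x_i), for all pixels."""
    logpsi = log_bounded(np.atleast_2d(x), params, np.atleast_2d(indicator))
    return np.einsum("il,il->i", params.eta[:, cluster, :],
                     np.exp(logpsi[:, cluster, :]))


def posteriors(x: np.ndarray, params: MixtureParams,
               indicator: np.ndarray) -> Posteriors:
    """Soft responsibilities z_ik (cluster) and y_ikl (component).

    Computed with log-sum-exp. A pixel whose indicator vanishes for every
    cluster has a degenerate bounded density everywhere; its
    responsibilities are recovered from the untruncated Gaussian mixture
    instead (uniform only if even that underflows), so the pixel is not
    reduced to a coin flip in the downstream updates.
    """
    logpsi = log_bounded(x, params, indicator)
    logeta = np.log(np.maximum(params.eta, DENSITY_FLOOR))
    logpi = np.log(np.maximum(params.pi, DENSITY_FLOOR))

    num_y = logeta + logpsi
    log_mix = logsumexp(num_y, axis=2)  # log sum_l eta Psi, (N, K)
    dead = np.all(np.asarray(indicator) <= 0.0, axis=1)
    if np.any(dead):
        logphi = log_gaussian(x[dead], params.mu, params.sigma)
        num_y[dead] = logeta[dead] + logphi
        log_mix[dead] = logsumexp(num_y[dead], axis=2)

    y = np.exp(num_y - logsumexp(num_y, axis=2, keepdims=True))
    num_z = logpi + log_mix
    z = np.exp(num_z - logsumexp(num_z, axis=1, keepdims=True))

    still_dead = np.all(log_mix <= _LOG_FLOOR + 1.0, axis=1)
    if np.any(still_dead):
        warnings.warn(f"{int(still_dead.sum())} pixel(s) had zero density under "
                      "every cluster; using uniform responsibilities")
        z[still_dead] = 1.0 / params.n_clusters
        y[still_dead] = 1.0 / params.n_components
    return Posteriors(z=z, y=y)


def objective(x: np.ndarray, params: MixtureParams, indicator: np.ndarray,
              E: np.ndarray, F: np.ndarray) -> float:
    """Negative penalized log-likelihood used for the convergence trace.

    J = -[ sum_i log sum_k pi_ik sum_l eta_ikl Psi_kl(x_i)
           + sum_ik E_ik log pi_ik + sum_ikl F_ikl log eta_ikl ].
    """
    logpsi = log_bounded(x, params, indicator)
    logeta = np.log(np.maximum(params.eta, DENSITY_FLOOR))
    logpi = np.log(np.maximum(params.pi, DENSITY_FLOOR))
    loglik = logsumexp(logpi + logsumexp(logeta + logpsi, axis=2), axis=1).sum()
    prior = np.sum(E * logpi) + np.sum(F * logeta)
    return float(-(loglik + prior))
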