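"""Gaussian process probit classification and KLD feature importance.

The binary class labels ``y`` are modelled through a probit link on a latent
Gaussian process ``f ~ N(0, K)`` with a radial basis function kernel
``K_ii' = exp(-theta * ||x_i - x_i'||^2)``, the bandwidth set by the median
criterion.  The intractable posterior ``p(f | y)`` is sampled with elliptical
slice sampling.  Posterior draws of ``f`` are projected to per-feature effect
sizes ``beta = pinv(X) f``, and each feature is scored by the Kullback-Leibler
divergence between the joint effect posterior and its conditional with that
effect set to zero; normalizing the KLD values to the simplex yields the
association measures ``gamma``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def median_bandwidth(X: np.ndarray) -> float:
    """Median-criterion bandwidth: 1 / (2 * median pairwise squared distance)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sq = pdist(X, metric="sqeuclidean")
    med = float(np.median(sq))
    if med == 0.0:
        raise ValueError("degenerate design: median pairwise distance is zero")
    return 1.0 / (2.0 * med)


def rbf_kernel(X: np.ndarray, bandwidth: float) -> np.ndarray:
    """RBF kernel matrix exp(-bandwidth * ||x_i - x_j||^2)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sq = squareform(pdist(np.asarray(X, dtype=float), metric="sqeuclidean"))
    return np.exp(-bandwidth * sq)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class GPCModel:
    """Gaussian process probit classifier state.

    Sampler settings: ``n_iter`` total elliptical-slice iterations, of which
    the first ``burn_in`` fraction is discarded and the remainder thinned by
    ``thin``, leaving ``S`` retained draws.
    """

    y: np.ndarray
    K: np.ndarray
    bandwidth: float
    n_iter: int = 20_000
    burn_in: float = 0.5
    thin: int = 5
    seed: int = 0
    jitter: float = 1e-6
    f_samples: Optional[np.ndarray] = None
    loglik_trace: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.K = np.asarray(self.K, dtype=float)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        eigmin = float(np.linalg.eigvalsh(self.K).min())
        if eigmin < -1e-8:
            raise ValueError(f"kernel matrix is not PSD (min eigenvalue {eigmin:.3e})")

    @classmethod
    def from_design(cls, X: np.ndarray, y: np.ndarray, **kwargs) -> "GPCModel":
        bw = kwargs.pop("bandwidth", None) or median_bandwidth(X)
        return cls(y=y, K=rbf_kernel(X, bw), bandwidth=bw, **kwargs)


def _probit_loglik(y_signed: np.ndarray) -> Callable[[np.ndarray], float]:
    def loglik(f: np.ndarray) -> float:
        return float(norm.logcdf(y_signed * f).sum())

    return loglik


def ess_sample(model: GPCModel,
               loglik: Optional[Callable[[np.ndarray], float]] = None) -> np.ndarray:
    """Draw posterior samples of the latent ``f`` by elliptical slice sampling.

    Returns an (S, N) array of retained, thinned draws and stores them (and
    the log-likelihood trace of every iteration) on the model.  Passing a
    custom ``loglik`` replaces the Bernoulli-probit likelihood (a constant
    function recovers the prior, which is used as a sampler correctness
    check).
    """
    n = model.K.shape[0]
    rng = np.random.default_rng(model.seed)
    jitter = model.jitter
    L = None
    while L is None:
        try:
            L = cholesky(model.K + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 10
            if jitter > 1e-2:
                raise np.linalg.LinAlgError(
                    "Cholesky factorization failed even after jitter escalation"
                )
    if loglik is None:
        loglik = _probit_loglik(2.0 * model.y - 1.0)

    f = np.zeros(n)
    cur_ll = loglik(f)
    n_burn = int(model.burn_in * model.n_iter)
    samples = []
    trace = np.empty(model.n_iter)
    for it in range(model.n_iter):
        nu = L @ rng.standard_normal(n)
        log_u = cur_ll + np.log(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        theta_min, theta_max = theta - 2.0 * np.pi, theta
        while True:
            f_prop = f * np.cos(theta) + nu * np.sin(theta)
            ll = loglik(f_prop)
            if ll > log_u:
                f, cur_ll = f_prop, ll
                break
            if theta < 0:
                theta_min = theta
            else:
                theta_max = theta
            theta = rng.uniform(theta_min, theta_max)
        trace[it] = cur_ll
        if it >= n_burn and (it - n_burn) % model.thin == 0:
            samples.append(f.copy())
    model.f_samples = np.array(samples)
    model.loglik_trace = trace
    return model.f_samples


# ---------------------------------------------------------------------------
# effect-size projection
# ---------------------------------------------------------------------------

@dataclass
class EffectPosterior:
    """Empirical moments of the projected effect sizes beta = pinv(X) f."""

    beta_samples: np.ndarray   # (S, J)
    mu: np.ndarray             # (J,)
    Sigma: np.ndarray          # (J, J)
    Lambda: np.ndarray         # (J, J) spectral pseudoinverse of Sigma

    @property
    def n_features(self) -> int:
        return self.mu.shape[0]

    # partition accessors (Sigma/Lambda with feature j singled out)
    def sigma_jj(self, j: int) -> float:
        return float(self.Sigma[j, j])

    def sigma_minus(self, j: int) -> np.ndarray:
        return np.delete(self.Sigma[:, j], j)

    def lambda_jj(self, j: int) -> float:
        return float(self.Lambda[j, j])

    def lambda_minus(self, j: int) -> np.ndarray:
        return np.delete(self.Lambda[:, j], j)

    def Sigma_minus(self, j: int) -> np.ndarray:
        return np.delete(np.delete(self.Sigma, j, axis=0), j, axis=1)

    def Lambda_minus(self, j: int) -> np.ndarray:
        return np.delete(np.delete(self.Lambda, j, axis=0), j, axis=1)


def _spectral_pinv(A: np.ndarray, rcond: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(A)
    cutoff = rcond * vals.max() if vals.size else 0.0
    inv = np.where(vals > cutoff, 1.0 / np.where(vals > cutoff, vals, 1.0), 0.0)
    return (vecs * inv) @ vecs.T


def project_effects(X: np.ndarray, f_samples: np.ndarray,
                    rcond: float = 1e-10, lambda_rcond: float = 1e-8) -> EffectPosterior:
    """Project latent draws to effect sizes via the minimum-norm projection.

    Each sample is mapped through the Moore-Penrose pseudoinverse of ``X``
    (SVD with relative cutoff ``rcond``); the posterior mean, covariance, and
    spectral pseudo-precision are the empirical moments over samples.
    """
    f_samples = np.atleast_2d(np.asarray(f_samples, dtype=float))
    if f_samples.shape[0] < 2:
        raise ValueError("need at least 2 samples for a covariance")
    Xp = np.linalg.pinv(np.asarray(X, dtype=float), rcond=rcond)
    beta = f_samples @ Xp.T
    mu = beta.mean(axis=0)
    centered = beta - mu
    Sigma = centered.T @ centered / (beta.shape[0] - 1)
    Lambda = _spectral_pinv(Sigma, rcond=lambda_rcond)
    return EffectPosterior(beta_samples=beta, mu=mu, Sigma=Sigma, Lambda=Lambda)


# ---------------------------------------------------------------------------
# KLD association measures
# ---------------------------------------------------------------------------

@dataclass
class AssociationScores:
    kld: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray

    def to_frame(self, design=None):
        import pandas as pd

        df = pd.DataFrame(
            {"feature_index": np.arange(len(self.kld)),
             "kld": self.kld, "gamma": self.gamma}
        )
        if design is not None:
            prov = design.provenance_table()
            df = prov.merge(df, on="feature_index")
        return df


def reduced_precision(Lambda: np.ndarray, j: int) -> np.ndarray:
    """Precision of the reduced system: pinv(Sigma with row/col j deleted).

    Computed by the exact rank-1 downdate of the full precision,
    ``[Lambda - lambda_j lambda_j^T / Lambda_jj]`` with row/column ``j``
    removed, avoiding a fresh matrix inversion per feature.
    """
    col = Lambda[:, j]
    piv = Lambda[j, j]
    if abs(piv) < 1e-14:
        raise np.linalg.LinAlgError("pivot Lambda_jj is numerically zero")
    omega = Lambda - np.outer(col, col) / piv
    return np.delete(np.delete(omega, j, axis=0), j, axis=1)


def conditional_covariance(Sigma: np.ndarray, j: int) -> np.ndarray:
    """Covariance of beta_{-j} given beta_j: rank-1 downdate of Sigma_{-j}."""
    sjj = Sigma[j, j]
    s_col = np.delete(Sigma[:, j], j)
    S_minus = np.delete(np.delete(Sigma, j, axis=0), j, axis=1)
    if sjj <= 1e-14:
        return S_minus
    return S_minus - np.outer(s_col, s_col) / sjj


def _alpha_vector(post: EffectPosterior) -> np.ndarray:
    """alpha_j = lambda_{-j}^T Cov(beta_{-j} | beta_j) lambda_{-j}, all j.

    Uses the closed-form rank-1 structure of the conditional covariance so the
    whole vector costs one J x J matmul instead of J matrix inversions.
    """
    Sigma, Lambda = post.Sigma, post.Lambda
    M = Sigma @ Lambda                      # M_ij = sigma_i . lambda_j
    d1 = np.einsum("ij,ij->j", Lambda, M)   # lambda_j^T Sigma lambda_j
    mjj = np.diag(M)                        # sigma_j . lambda_j
    ljj = np.diag(Lambda)
    sjj = np.diag(Sigma)
    term = d1 - 2.0 * ljj * mjj + ljj**2 * sjj       # lambda_{-j}^T Sigma_{-j} lambda_{-j}
    cross = mjj - ljj * sjj                           # lambda_{-j}^T sigma_{-j}
    with np.errstate(divide="ignore", invalid="ignore"):
        downdate = np.where(sjj > 1e-14, cross**2 / np.where(sjj > 0, sjj, 1.0), 0.0)
    alpha = np.maximum(term - downdate, 0.0)
    # snap pure floating-point residue (e.g. exactly independent features,
    # where every alpha is analytically zero) to zero
    if alpha.max() <= 1e-10:
        alpha[:] = 0.0
    return alpha


def kld_scores(post: EffectPosterior, mode: str = "approx") -> AssociationScores:
    """Per-feature KLD importance and simplex-normalized gamma.

    ``mode='approx'`` scores each feature by ``alpha_j mu_j^2 / 2`` (the KLD
    evaluated at ``beta_j = 0`` with the log-det and trace terms dropped);
    ``mode='full'`` adds those terms, giving the exact Gaussian KL between the
    marginal effect posterior and its conditional at ``beta_j = 0``.
    """
    if mode not in ("approx", "full"):
        raise ValueError("mode must be 'approx' or 'full'")
    J = post.n_features
    alpha = _alpha_vector(post)
    kld = alpha * post.mu**2 / 2.0
    if mode == "full":
        extra = np.empty(J)
        for j in range(J):
            prod = post.Sigma_minus(j) @ post.Lambda_minus(j)
            sign, logdet = np.linalg.slogdet(prod)
            if sign <= 0:
                warnings.warn(f"non-positive determinant at feature {j}; using |det|")
            extra[j] = 0.5 * (-logdet + np.trace(prod) + 1.0 - J)
        kld = kld + extra
    kld = np.maximum(kld, 0.0)
    total = kld.sum()
    if total <= 0:
        gamma = np.full(J, 1.0 / J)
    else:
        gamma = kld / total
    return AssociationScores(kld=kld, gamma=gamma, alpha=alpha)
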