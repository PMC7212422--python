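"""Rectified factor network: factor analysis with posterior-regularized codes.

The generative model is the classical factor-analysis model

    V_i = W h_i + eps_i,     h_i ~ N(0, I_r),   eps_i ~ N(0, diag(psi)),

fit by maximum likelihood through a generalized alternating-minimization
(variational EM) scheme.  The twist that turns factor analysis into a
biclustering engine is posterior regularization: the variational posterior
means mu_i are constrained to be non-negative and, per hidden unit j,
normalized to unit mean square across samples, (1/n) sum_i mu_ij^2 = 1.
Rectification produces sparse codes, so each hidden unit j ends up loading
on a subset of genes (column j of W) and being active in a subset of
samples (row j of the code matrix) -- a bicluster candidate.

With rectification disabled the E-step uses the exact Gaussian posterior
means and the procedure reduces to textbook factor-analysis EM, which is the
correctness anchor used by the test-suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "PosteriorStats",
    "EMConfig",
    "RFNFit",
    "init_model",
    "compute_posterior",
    "project_means",
    "m_step",
    "log_likelihood",
    "fit_rfn",
]


@dataclass
class FactorModel:
    """Loadings ``W`` (m genes x r hidden units) and diagonal noise ``psi``.

    ``psi`` holds the diagonal of the noise covariance; it is kept at or
    above a strictly positive floor so the marginal covariance W W^T + Psi
    is always positive definite.
    """

    W: np.ndarray
    psi: np.ndarray

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def r(self) -> int:
        return self.W.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.W)):
            raise FloatingPointError("non-finite entries in loading matrix W")
        if not np.all(np.isfinite(self.psi)) or np.any(self.psi <= 0):
            raise FloatingPointError("noise variances must be finite and positive")


class PosteriorStats(NamedTuple):
    """Gaussian posterior of the hidden units given the (centered) data.

    ``mu_p`` is r x n (one posterior-mean column per sample); ``K_pp`` is the
    r x r posterior covariance, shared across samples because the model is
    homoscedastic in h.
    """

    mu_p: np.ndarray
    K_pp: np.ndarray


@dataclass
class EMConfig:
    """Knobs of the alternating-minimization fit.

    Parameters
    ----------
    n_iters : int
        Maximum number of E/M alternations.
    psi_floor : float
        Lower bound kept on every noise variance.
    dropout_rate : float
        Probability of masking each hidden unit's codes in a given M-step;
        a sparsity device, disabled at 0.
    l1_weight : float
        Laplace-prior strength on W, realized as soft-thresholding of the
        updated loadings.
    seed : int
        Seed for dropout masks (the only randomness inside the fit).
    rectify : bool
        If False, skip the posterior projection: classical factor analysis.
    tol : float
        Early-stopping threshold on the relative log-likelihood change;
        0 disables early stopping.
    """

    n_iters: int = 100
    psi_floor: float = 1e-4
    dropout_rate: float = 0.1
    l1_weight: float = 0.01
    seed: int = 0
    rectify: bool = True
    tol: float = 1e-6


@dataclass
class RFNFit:
    """Result of :func:`fit_rfn`: final model, final codes, objective trace."""

    model: FactorModel
    means: np.ndarray  # r x n rectified variational means (sample memberships)
    loglik: list[float] = field(default_factory=list)
    n_iters_run: int = 0


def init_model(m: int, r: int, seed: int, data: np.ndarray | None = None) -> FactorModel:
    """Random small-scale loadings; noise set to per-gene data variance.

    ``W`` entries are i.i.d. normal with scale 0.1/sqrt(r) so the initial
    signal covariance W W^T is small relative to the noise.  Without data,
    psi starts at 1.
    """
    if m < 2:
        raise ValueError(f"need at least 2 genes, got m={m}")
    if r < 1:
        raise ValueError(f"need at least 1 hidden unit, got r={r}")
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.1 / np.sqrt(r), size=(m, r))
    if data is None:
        psi = np.ones(m)
    else:
        if data.shape[0] != m:
            raise ValueError("data row count does not match m")
        psi = np.maximum(np.var(data, axis=1), 1e-4)
    return FactorModel(W=W, psi=psi)


def compute_posterior(model: FactorModel, V: np.ndarray) -> PosteriorStats:
    """Exact Gaussian posterior of h given mean-centered data V (m x n).

    K_pp = (I + W^T Psi^-1 W)^-1 and mu_p[:, i] = K_pp W^T Psi^-1 V_i.
    """
    if V.shape[0] != model.m:
        raise ValueError(
            f"data has {V.shape[0]} rows but model expects {model.m} genes"
        )
    model.validate()
    Wt_PsiInv = (model.W / model.psi[:, None]).T  # r x m
    A = np.eye(model.r) + Wt_PsiInv @ model.W
    A = 0.5 * (A + A.T)
    c, low = linalg.cho_factor(A)
    K_pp = linalg.cho_solve((c, low), np.eye(model.r))
    K_pp = 0.5 * (K_pp + K_pp.T)
    mu_p = linalg.cho_solve((c, low), Wt_PsiInv @ V)
    return PosteriorStats(mu_p=mu_p, K_pp=K_pp)


def project_means(stats: PosteriorStats) -> np.ndarray:
    """Euclidean projection of the posterior means onto the code constraints.

    Minimizes sum_i ||mu_i - (mu_p)_i||^2 subject to mu >= 0 and, per hidden
    unit j, (1/n) sum_i mu_ij^2 = 1.  The constraint set separates over
    hidden-unit rows, and on each row the minimizer is: clip negatives to
    zero, then rescale the row onto the sphere of squared mean 1.  A row
    with no positive entry is annihilated by the rectification and is left
    at zero (an inactive unit; the normalization is vacuous for it).
    """
    mu_p = stats.mu_p
    n = mu_p.shape[1]
    mu = np.maximum(mu_p, 0.0)
    rms = np.sqrt(np.sum(mu * mu, axis=1) / n)
    active = rms > 0
    mu[active] /= rms[active, None]
    return mu


def m_step(
    V: np.ndarray,
    mu: np.ndarray,
    K_pp: np.ndarray,
    config: EMConfig,
    iteration: int = 0,
) -> FactorModel:
    """Update (W, psi) to decrease the expected reconstruction error.

    With P = (1/n) sum_i V_i mu_i^T, Z = (1/n) sum_i mu_i mu_i^T + K_pp and
    C = (1/n) sum_i V_i V_i^T the updates are W_new = P Z^-1 (optionally
    soft-thresholded by ``l1_weight``) and psi_new = diag(C - P W^T - W P^T
    + W Z W^T), floored at ``psi_floor``.  If ``dropout_rate`` > 0 a random
    subset of hidden units is masked in mu before the update; the mask is
    deterministic given (config.seed, iteration).
    """
    m, n = V.shape
    r = mu.shape[0]
    if mu.shape[1] != n or K_pp.shape != (r, r):
        raise ValueError("inconsistent shapes in M-step inputs")

    if config.dropout_rate > 0:
        rng = np.random.default_rng((config.seed, iteration))
        keep = rng.random(r) >= config.dropout_rate
        if not keep.any():
            keep[rng.integers(r)] = True  # never drop every unit
        mu = mu * keep[:, None]

    P = V @ mu.T / n  # m x r
    Z = mu @ mu.T / n + K_pp
    Z = 0.5 * (Z + Z.T)
    try:
        c, low = linalg.cho_factor(Z)
    except linalg.LinAlgError:
        logger.warning("singular Z in M-step; adding 1e-6 ridge")
        Z = Z + 1e-6 * np.eye(r)
        c, low = linalg.cho_factor(Z)
    W_new = linalg.cho_solve((c, low), P.T).T  # P Z^-1

    if config.l1_weight > 0:
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - config.l1_weight, 0.0)

    # diag(C - P W^T - W P^T + W Z W^T) without forming C
    diag_C = np.einsum("ij,ij->i", V, V) / n
    psi_new = (
        diag_C
        - 2.0 * np.einsum("ij,ij->i", P, W_new)
        + np.einsum("ij,ij->i", W_new @ Z, W_new)
    )
    psi_new = np.maximum(psi_new, config.psi_floor)
    return FactorModel(W=W_new, psi=psi_new)


def log_likelihood(model: FactorModel, V: np.ndarray) -> float:
    """Marginal Gaussian log-likelihood of V under N(0, W W^T + Psi).

    Evaluated through the r-dimensional space (matrix-determinant lemma and
    Woodbury identity), so it stays cheap and stable for thousands of genes.
    """
    m, n = V.shape
    if m != model.m:
        raise ValueError("data/model dimension mismatch")
    W, psi = model.W, model.psi
    Wt_PsiInv = (W / psi[:, None]).T
    A = np.eye(model.r) + Wt_PsiInv @ W
    A = 0.5 * (A + A.T)
    c, low = linalg.cho_factor(A)
    logdet = np.sum(np.log(psi)) + 2.0 * np.sum(np.log(np.diag(c)))
    U = Wt_PsiInv @ V  # r x n
    quad = np.sum(V * V / psi[:, None]) - np.sum(U * linalg.cho_solve((c, low), U))
    return float(-0.5 * n * m * np.log(2.0 * np.pi) - 0.5 * n * logdet - 0.5 * quad)


def fit_rfn(V: np.ndarray, r: int, config: EMConfig) -> RFNFit:
    """Alternating minimization: posterior, projection (E), update (M).

    ``V`` must be the mean-centered data matrix (genes x samples).  Returns
    the final model together with the final rectified variational means,
    which double as the sample-membership matrix H used downstream for
    bicluster extraction.  Fully deterministic for a fixed config.
    """
    V = np.asarray(V, dtype=float)
    if np.isnan(V).any():
        raise ValueError("NaN entries in data matrix")
    model = init_model(V.shape[0], r, config.seed, data=V)
    mu = np.zeros((r, V.shape[1]))
    loglik: list[float] = []
    it = 0
    for it in range(1, config.n_iters + 1):
        stats = compute_posterior(model, V)
        mu = project_means(stats) if config.rectify else stats.mu_p
        model = m_step(V, mu, stats.K_pp, config, iteration=it)
        if not np.all(np.isfinite(model.W)):
            raise FloatingPointError(f"fit diverged (non-finite W) at iteration {it}")
        ll = log_likelihood(model, V)
        loglik.append(ll)
        if (
            config.tol > 0
            and len(loglik) > 1
            and abs(loglik[-1] - loglik[-2]) < config.tol * (1.0 + abs(loglik[-2]))
        ):
            break
    # report codes consistent with the final model
    stats = compute_posterior(model, V)
    mu = project_means(stats) if config.rectify else stats.mu_p
    return RFNFit(model=model, means=mu, loglik=loglik, n_iters_run=it)
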