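"""Model-evidence machinery: Laplace-Gibbs marginal likelihood, BIC, weights.

The marginal likelihood p(Y|M) = int p(Y|theta, M) p(theta|M) dtheta is
approximated by Laplace's asymptotic formula evaluated from Gibbs-sampler
output:

    log p(Y|M) ~= (d/2) log 2pi + (1/2) log|H*|
                  + log p(Y|theta*, M) + log p(theta*|M)

with theta* the posterior mean of the retained draws and H* the posterior
covariance, estimated blockwise from the same draws. Posterior model weights
follow by Bayes' theorem from the per-model log marginal likelihoods and a
prior over models (equal by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import FittedModel, SymptomMatrix, ValidationError
from .gom import gom_log_likelihood
from .lca import lca_log_likelihood

__all__ = [
    "EvidenceResult",
    "ModelWeights",
    "laplace_gibbs_logml",
    "evidence_for_fit",
    "model_weights",
    "bic",
    "parameter_dimension",
    "select_K",
]

EIG_FLOOR = 1e-10


@dataclass
class EvidenceResult:
    log_marginal_likelihood: float
    d: int
    theta_star: list[np.ndarray]
    log_det_H: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ModelWeights:
    prior: np.ndarray
    log_ml: np.ndarray
    weights: np.ndarray


def _block_log_det(block: np.ndarray, floor: float) -> tuple[float, int]:
    """Log-determinant of the sample covariance of one (T, b) draw block."""
    cov = np.atleast_2d(np.cov(block, rowvar=False))
    eigvals = np.linalg.eigvalsh(cov)
    n_floored = int((eigvals < floor).sum())
    return float(np.log(np.clip(eigvals, floor, None)).sum()), n_floored


def laplace_gibbs_logml(
    blocks: Sequence[np.ndarray],
    log_unnormalised_posterior: Callable[[Sequence[np.ndarray]], float],
    eig_floor: float = EIG_FLOOR,
) -> EvidenceResult:
    """Laplace approximation to the log evidence from posterior draws.

    Parameters
    ----------
    blocks : sequence of (T, b_i) arrays of retained posterior draws; the
        parameter vector theta is their concatenation and H* is taken
        block-diagonal (one sample-covariance block per entry), so
        log|H*| is the sum of blockwise log-determinants. Covariance
        eigenvalues are floored at ``eig_floor`` before the log.
    log_unnormalised_posterior : callable returning
        log p(Y|theta, M) + log p(theta|M) at a parameter point given as a
        list of per-block vectors (the posterior means are passed in).
    """
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    blocks = [b.reshape(b.shape[0], -1) if b.ndim > 2 else b for b in blocks]
    if not blocks or any(b.shape[0] < 2 for b in blocks):
        raise ValidationError("need at least two retained draws per block")
    d = sum(b.shape[1] for b in blocks)
    T = blocks[0].shape[0]
    if T < d // max(len(blocks), 1) + 1:
        warnings.warn("few retained draws relative to block dimension; covariance may be poor", stacklevel=2)

    theta_star = [b.mean(axis=0) for b in blocks]
    log_det = 0.0
    total_floored = 0
    for b in blocks:
        ld, nf = _block_log_det(b, eig_floor)
        log_det += ld
        total_floored += nf
    if total_floored:
        warnings.warn(f"{total_floored} covariance eigenvalue(s) floored at {eig_floor:g}", stacklevel=2)

    log_post = float(log_unnormalised_posterior(theta_star))
    logml = 0.5 * d * math.log(2.0 * math.pi) + 0.5 * log_det + log_post
    return EvidenceResult(
        log_marginal_likelihood=logml,
        d=d,
        theta_star=theta_star,
        log_det_H=log_det,
        diagnostics={"n_draws": T, "n_blocks": len(blocks), "n_floored_eigenvalues": total_floored},
    )


def _simplex_drop_last(draws: np.ndarray) -> np.ndarray:
    """Drop the redundant last simplex coordinate to keep covariance full rank."""
    return draws[..., :-1]


def _restore_simplex(vec: np.ndarray) -> np.ndarray:
    return np.append(vec, 1.0 - vec.sum())


def evidence_for_fit(fit: FittedModel, Y: SymptomMatrix) -> EvidenceResult:
    """Laplace-Gibbs evidence for an LCA or GoM fit; stores it on the fit.

    Block layout (H* block-diagonal):
      LCA: one (K-1)-dim block for p (last coordinate dropped) and one J-dim
           block per class for the lambda row; d = (K-1) + K*J.
      GoM: one J-dim block per class for the gamma row and one (K-1)-dim
           block per individual for the membership scores g_i (the scores
           carry priors and are sampled, so they count as parameters);
           d = K*J + n*(K-1).

    The prior density at theta* is the product of the flat Beta(1,1) terms
    (log 0) and the symmetric Dirichlet(1, ..., 1) normalising constants,
    log Gamma(K) per simplex.
    """
    K, J, n = fit.K, fit.J, fit.n
    if fit.model_tag == "LCA":
        lam_draws = fit.retained["lam"]  # (T, K, J)
        p_draws = fit.retained["p"]  # (T, K)
        blocks = [_simplex_drop_last(p_draws)] + [lam_draws[:, k, :] for k in range(K)]

        def log_unnorm(theta: Sequence[np.ndarray]) -> float:
            p = _restore_simplex(theta[0])
            lam = np.vstack(theta[1:])
            return lca_log_likelihood(Y, p, lam) + gammaln(K)

    elif fit.model_tag == "GoM":
        gam_draws = fit.retained["gam"]  # (T, K, J)
        g_draws = fit.retained["g"]  # (T, n, K)
        blocks = [gam_draws[:, k, :] for k in range(K)] + [
            _simplex_drop_last(g_draws[:, i, :]) for i in range(n)
        ]

        def log_unnorm(theta: Sequence[np.ndarray]) -> float:
            gam = np.vstack(theta[:K])
            g = np.vstack([_restore_simplex(v) for v in theta[K:]])
            return gom_log_likelihood(Y, gam, g) + n * gammaln(K)

    else:
        raise ValidationError(f"unknown model tag {fit.model_tag!r}")

    res = laplace_gibbs_logml(blocks, log_unnorm)
    fit.log_marginal_likelihood = res.log_marginal_likelihood
    return res


def model_weights(log_ml: Sequence[float], prior: Sequence[float] | None = None) -> ModelWeights:
    """Posterior model probabilities from log marginal likelihoods.

    weights_s propto exp(log_ml_s - max) * prior_s, normalised; stable under
    arbitrarily large |log_ml|. The prior defaults to equal probability per
    model.
    """
    log_ml = np.asarray(log_ml, dtype=float)
    S = log_ml.shape[0]
    prior_arr = np.full(S, 1.0 / S) if prior is None else np.asarray(prior, dtype=float)
    if prior_arr.shape != log_ml.shape or np.any(prior_arr < 0):
        raise ValidationError("prior must be nonnegative and align with log_ml")
    if prior_arr.sum() <= 0:
        raise ValidationError("at least one model must have positive prior probability")
    prior_arr = prior_arr / prior_arr.sum()
    with np.errstate(divide="ignore"):
        log_w = log_ml + np.log(prior_arr)
    log_w = log_w - log_w[np.isfinite(log_w)].max()
    w = np.where(np.isfinite(log_w), np.exp(log_w), 0.0)
    w = w / w.sum()
    return ModelWeights(prior=prior_arr, log_ml=log_ml, weights=w)


def bic(max_log_likelihood: float, d: int, n: int) -> float:
    """Bayesian information criterion, -2 l_hat + d log n (lower is better)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return -2.0 * max_log_likelihood + d * math.log(n)


def parameter_dimension(model_tag: str, K: int, J: int, n: int) -> int:
    """Free-parameter count: LCA (K-1) + K*J; GoM K*J + n*(K-1)."""
    if model_tag == "LCA":
        return (K - 1) + K * J
    if model_tag == "GoM":
        return K * J + n * (K - 1)
    raise ValidationError(f"unknown model tag {model_tag!r}")


def select_K(
    Y: SymptomMatrix,
    model_tag: str,
    K_range: Sequence[int] = range(2, 7),
    fit_settings: dict | None = None,
) -> tuple[int, pd.DataFrame]:
    """Fit each K in K_range and pick the BIC minimiser.

    No monotonicity of the BIC curve is assumed; only the argmin is
    returned, together with the full table.
    """
    from .gom import fit_gom
    from .lca import fit_lca

    K_range = list(K_range)
    if not K_range:
        raise ValidationError("K_range must be non-empty")
    fitter = {"LCA": fit_lca, "GoM": fit_gom}.get(model_tag)
    if fitter is None:
        raise ValidationError(f"unknown model tag {model_tag!r}")
    settings = dict(fit_settings or {})
    rows = []
    for K in K_range:
        fit = fitter(Y, K=K, **settings)
        d = parameter_dimension(model_tag, K, Y.J, Y.n)
        rows.append(
            {
                "K": K,
                "d": d,
                "max_log_likelihood": fit.max_log_likelihood,
                "bic": bic(fit.max_log_likelihood, d, Y.n),
            }
        )
    table = pd.DataFrame(rows)
    K_best = int(table.loc[table["bic"].idxmin(), "K"])
    return K_best, table
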