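"""Latent class analysis: a finite mixture of Bernoulli products fit by Gibbs.

Model: individual i belongs to exactly one of K latent classes; given class
k, the J binary symptoms are independent Bernoulli(lambda_kj). Priors are
non-informative: class proportions p ~ Dirichlet(1, ..., 1), symptom rates
lambda_kj ~ Beta(1, 1). All full conditionals are conjugate, so the sampler
is a pure Gibbs scheme:

    z_i  ~ Multinomial(delta_i1, ..., delta_iK),
           delta_ik = p_k f(Y_i | lambda_k.) / sum_l p_l f(Y_i | lambda_l.)
    p    ~ Dirichlet(sum_i z_i1 + 1, ..., sum_i z_iK + 1)
    lam  ~ Beta(sum_i z_ik y_ij + 1, sum_i z_ik (1 - y_ij) + 1)

delta_ik is the posterior membership probability of individual i, and its
post-burn-in average is the per-individual phenotype estimate phi_i1 used in
model averaging (Rao-Blackwellised: averaging delta has lower variance than
averaging the one-hot z draws).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datatypes import FittedModel, SymptomMatrix, ValidationError
from .mcmc import chain_seeds, relabel

__all__ = ["LCAState", "lca_log_likelihood", "lca_gibbs_step", "fit_lca"]

# guard against log(0): Beta(1,1) posteriors put zero mass exactly on the
# boundary but floating point can land there
PROB_EPS = 1e-12


@dataclass
class LCAState:
    p: np.ndarray  # (K,) class proportions
    lam: np.ndarray  # (K, J) symptom rates
    z: np.ndarray  # (n, K) one-hot class indicators
    delta: np.ndarray  # (n, K) membership probabilities


def _as_matrix(Y) -> np.ndarray:
    vals = Y.values if isinstance(Y, SymptomMatrix) else np.asarray(Y)
    return vals.astype(float)


def _class_log_densities(Yv: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """(n, K) log f(Y_i | lambda_k.) for each individual and class."""
    lam_c = np.clip(lam, PROB_EPS, 1.0 - PROB_EPS)
    return Yv @ np.log(lam_c).T + (1.0 - Yv) @ np.log1p(-lam_c).T


def _membership_logits(Yv: np.ndarray, p: np.ndarray, lam: np.ndarray) -> np.ndarray:
    logp = np.full_like(np.asarray(p, float), -np.inf)
    np.log(p, out=logp, where=np.asarray(p) > 0)
    return _class_log_densities(Yv, lam) + logp


def lca_log_likelihood(Y, p, lam) -> float:
    """Mixture log-likelihood sum_i log sum_k p_k prod_j Bern(y_ij | lambda_kj)."""
    Yv = _as_matrix(Y)
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 2 or p.ndim != 1 or lam.shape[0] != p.shape[0] or lam.shape[1] != Yv.shape[1]:
        raise ValidationError("dimension mismatch between Y, p and lam")
    return float(logsumexp(_membership_logits(Yv, p, lam), axis=1).sum())


def _sample_categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Draw one index per row of a row-stochastic matrix."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def lca_gibbs_step(state: LCAState, Y, rng: np.random.Generator) -> LCAState:
    """One full conjugate Gibbs sweep: z, then p, then lambda."""
    Yv = _as_matrix(Y)
    n, _ = Yv.shape
    K = state.p.shape[0]

    logits = _membership_logits(Yv, state.p, state.lam)
    delta = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    idx = _sample_categorical_rows(rng, delta)
    z = np.zeros((n, K))
    z[np.arange(n), idx] = 1.0

    p = rng.dirichlet(z.sum(axis=0) + 1.0)
    a = z.T @ Yv + 1.0
    b = z.T @ (1.0 - Yv) + 1.0
    lam = rng.beta(a, b)
    return LCAState(p=p, lam=lam, z=z, delta=delta)


def _initial_state(rng: np.random.Generator, Yv: np.ndarray, K: int) -> LCAState:
    """Chain start: k-means partition of the rows, profiles from cluster means.

    A purely random start almost never lands in the basin of the dominant
    mode on well-separated data, and plain Gibbs cannot split a merged
    cluster once its profile sharpens; seeding from a (per-chain randomly
    initialised) k-means partition fixes that while keeping chains
    dispersed. Profiles are shrunk away from the boundaries so the first
    sweeps stay mobile.
    """
    n, J = Yv.shape
    try:
        from scipy.cluster.vq import kmeans2

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, labels = kmeans2(Yv + 1e-6 * rng.random(Yv.shape), K, minit="++", seed=rng)
    except Exception:
        labels = rng.integers(K, size=n)
    z = np.zeros((n, K))
    z[np.arange(n), labels] = 1.0
    counts = z.sum(axis=0)
    lam = np.clip((z.T @ Yv + 1.0) / (counts[:, None] + 2.0), 0.1, 0.9)
    p = (counts + 1.0) / (n + K)
    return LCAState(p=p, lam=lam, z=z, delta=np.full((n, K), 1.0 / K))


def fit_lca(
    Y: SymptomMatrix,
    K: int,
    n_iter: int = 20_000,
    burn_in: int = 10_000,
    thin: int = 2,
    n_chains: int = 3,
    seed: int = 0,
) -> FittedModel:
    """Fit the K-class LCA by Gibbs sampling; pool chains after relabelling."""
    if K < 2:
        raise ValidationError("K must be >= 2")
    if burn_in >= n_iter:
        raise ValidationError("burn_in must be < n_iter")
    Yv = _as_matrix(Y)
    n, J = Yv.shape
    n_patterns = len({tuple(row) for row in np.asarray(Y.values)})
    if K > n_patterns:
        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct response patterns; the model is likely non-identifiable",
            stacklevel=2,
        )

    lam_draws, p_draws, delta_draws = [], [], []
    deviance = np.empty((n_chains, n_iter))
    for c, rng in enumerate(chain_seeds(seed, n_chains)):
        state = _initial_state(rng, Yv, K)
        for t in range(n_iter):
            state = lca_gibbs_step(state, Yv, rng)
            deviance[c, t] = -2.0 * lca_log_likelihood(Yv, state.p, state.lam)
            if t >= burn_in and (t - burn_in) % thin == 0:
                lam_draws.append(state.lam)
                p_draws.append(state.p)
                delta_draws.append(state.delta)

    lam_arr, p_arr, delta_arr = relabel(
        np.asarray(lam_draws), np.asarray(p_draws), np.asarray(delta_draws)
    )
    phi = delta_arr.mean(axis=0)
    phi /= phi.sum(axis=1, keepdims=True)
    return FittedModel(
        model_tag="LCA",
        K=K,
        individual_ids=tuple(Y.individual_ids),
        symptom_labels=tuple(Y.symptom_labels),
        profiles=lam_arr.mean(axis=0),
        phi=phi,
        deviance_trace=deviance,
        retained={"lam": lam_arr, "p": p_arr},
        max_log_likelihood=float(-0.5 * deviance[:, burn_in:].min()),
        settings={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "n_chains": n_chains,
            "seed": seed,
        },
    )
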