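"""Grade-of-membership model fit by Gibbs sampling with latent class labels.

Model: individual i carries a membership vector g_i on the K-simplex, and
symptom j is present with probability sum_k g_ik gamma_kj. Priors are
non-informative: g_i ~ Dirichlet(1, ..., 1) per individual and
gamma_kj ~ Beta(1, 1). Conjugacy is recovered by augmenting with a
per-individual, per-symptom class label omega_ij in {1..K}:

    omega_ij ~ Multinomial(kappa_ij1, ..., kappa_ijK),
               kappa_ijk propto g_ik gamma_kj^{y_ij} (1 - gamma_kj)^{1 - y_ij}
    g_i      ~ Dirichlet(sum_j omega_ij1 + 1, ..., sum_j omega_ijK + 1)
    gamma_kj ~ Beta(sum_i omega_ijk y_ij + 1, sum_i omega_ijk (1 - y_ij) + 1)

The posterior mean of g_ik over retained relabelled draws is the
per-individual phenotype estimate phi_i2 used in model averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import FittedModel, SymptomMatrix, ValidationError
from .lca import PROB_EPS, _as_matrix
from .mcmc import chain_seeds, relabel

__all__ = ["GoMState", "gom_log_likelihood", "gom_gibbs_step", "fit_gom"]


@dataclass
class GoMState:
    gam: np.ndarray  # (K, J) symptom rates per class
    g: np.ndarray  # (n, K) membership scores, rows on the simplex
    omega: np.ndarray  # (n, J) symptom-level class labels in {0..K-1}


def gom_log_likelihood(Y, gam, g) -> float:
    """sum_ij [ y_ij log(sum_k g_ik gamma_kj) + (1-y_ij) log(1 - sum_k g_ik gamma_kj) ]."""
    Yv = _as_matrix(Y)
    gam = np.asarray(gam, dtype=float)
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or gam.ndim != 2 or g.shape[0] != Yv.shape[0] or gam.shape[1] != Yv.shape[1] or g.shape[1] != gam.shape[0]:
        raise ValidationError("dimension mismatch between Y, gam and g")
    mix = np.clip(g @ gam, PROB_EPS, 1.0 - PROB_EPS)  # (n, J)
    return float((Yv * np.log(mix) + (1.0 - Yv) * np.log1p(-mix)).sum())


def gom_gibbs_step(state: GoMState, Y, rng: np.random.Generator) -> GoMState:
    """One augmented Gibbs sweep: omega, then g, then gamma."""
    Yv = _as_matrix(Y)
    n, J = Yv.shape
    K = state.gam.shape[0]

    # kappa_ijk propto g_ik * gamma_kj^y * (1-gamma_kj)^(1-y)
    lik = np.where(Yv[:, :, None] == 1.0, state.gam.T[None, :, :], 1.0 - state.gam.T[None, :, :])
    kappa = state.g[:, None, :] * lik  # (n, J, K)
    kappa /= kappa.sum(axis=2, keepdims=True)

    cum = np.cumsum(kappa, axis=2)
    cum[:, :, -1] = 1.0
    u = rng.random((n, J))
    omega = (u[:, :, None] > cum).sum(axis=2)  # (n, J)

    onehot = omega[:, :, None] == np.arange(K)[None, None, :]  # (n, J, K)
    counts = onehot.sum(axis=1)  # (n, K)
    gamma_vars = rng.standard_gamma(counts + 1.0)
    g = gamma_vars / gamma_vars.sum(axis=1, keepdims=True)

    a = (onehot * Yv[:, :, None]).sum(axis=0).T + 1.0  # (K, J)
    b = (onehot * (1.0 - Yv)[:, :, None]).sum(axis=0).T + 1.0
    gam = rng.beta(a, b)
    return GoMState(gam=gam, g=g, omega=omega)


def _initial_state(rng: np.random.Generator, n: int, J: int, K: int) -> GoMState:
    gam = rng.uniform(0.2, 0.8, size=(K, J))
    g = rng.dirichlet(np.ones(K), size=n)
    omega = rng.integers(K, size=(n, J))
    return GoMState(gam=gam, g=g, omega=omega)


def fit_gom(
    Y: SymptomMatrix,
    K: int,
    n_iter: int = 20_000,
    burn_in: int = 10_000,
    thin: int = 2,
    n_chains: int = 3,
    seed: int = 0,
) -> FittedModel:
    """Fit the K-class GoM by augmented Gibbs sampling; pool relabelled chains.

    Only the g and gamma draws are retained (the omega labels are discarded
    each sweep), so memory scales with the number of retained draws.
    """
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

    gam_draws, g_draws = [], []
    deviance = np.empty((n_chains, n_iter))
    for c, rng in enumerate(chain_seeds(seed, n_chains)):
        state = _initial_state(rng, n, J, K)
        for t in range(n_iter):
            state = gom_gibbs_step(state, Yv, rng)
            deviance[c, t] = -2.0 * gom_log_likelihood(Yv, state.gam, state.g)
            if t >= burn_in and (t - burn_in) % thin == 0:
                gam_draws.append(state.gam)
                g_draws.append(state.g)

    gam_arr, _, g_arr = relabel(np.asarray(gam_draws), None, np.asarray(g_draws))
    phi = g_arr.mean(axis=0)
    phi /= phi.sum(axis=1, keepdims=True)
    return FittedModel(
        model_tag="GoM",
        K=K,
        individual_ids=tuple(Y.individual_ids),
        symptom_labels=tuple(Y.symptom_labels),
        profiles=gam_arr.mean(axis=0),
        phi=phi,
        deviance_trace=deviance,
        retained={"gam": gam_arr, "g": g_arr},
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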