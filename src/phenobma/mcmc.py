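"""Shared MCMC utilities: relabelling and chain seeding.

Mixture posteriors are invariant under permutation of cluster labels, so raw
Gibbs output may switch labels between iterations (and chains started from
different points typically land in different label modes). ``relabel``
aligns every retained draw to a running mean profile before posterior
summaries are taken.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["relabel", "chain_seeds"]


def relabel(
    profile_draws: np.ndarray,
    simplex_draws: np.ndarray | None = None,
    membership_draws: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Align cluster labels across draws by matching profiles to a running mean.

    For each draw t, the cluster permutation minimising the total L1 distance
    between that draw's (K, J) profile rows and the running mean profile is
    found by optimal assignment and applied consistently to the profile rows,
    the mixing-proportion entries and the membership columns. The running
    mean is updated after each aligned draw.

    Parameters
    ----------
    profile_draws : (T, K, J) symptom-rate draws (lambda for LCA, gamma for GoM)
    simplex_draws : optional (T, K) mixing-proportion draws
    membership_draws : optional (T, n, K) per-individual membership draws

    Returns relabelled copies in the same order.
    """
    prof = np.array(profile_draws, dtype=float)
    if prof.ndim != 3 or prof.shape[0] < 1:
        raise ValueError("profile_draws must be (T, K, J) with T >= 1")
    T, K, _ = prof.shape
    simp = None if simplex_draws is None else np.array(simplex_draws, dtype=float)
    memb = None if membership_draws is None else np.array(membership_draws, dtype=float)
    if K == 1:
        return prof, simp, memb

    ref = prof[0].copy()
    for t in range(T):
        # cost[k, l] = L1 distance of draw-cluster k to reference-cluster l
        cost = np.abs(prof[t][:, None, :] - ref[None, :, :]).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows  # reference slot l receives draw cluster perm[l]
        if not np.array_equal(perm, np.arange(K)):
            prof[t] = prof[t][perm]
            if simp is not None:
                simp[t] = simp[t][perm]
            if memb is not None:
                memb[t] = memb[t][:, perm]
        ref += (prof[t] - ref) / (t + 1)
    return prof, simp, memb


def chain_seeds(seed: int, n_chains: int) -> list[np.random.Generator]:
    """Independent generators for parallel chains, reproducible from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_chains)]
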