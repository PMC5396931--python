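"""Independent oracles used by the test suite.

These deliberately avoid the package's own samplers: exact posteriors come
from exhaustive enumeration with conjugate Dirichlet/Beta integrals, exact
evidences from closed forms or quadrature, and likelihoods from explicit
Python loops.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import betaln, gammaln, logsumexp


def loop_lca_log_likelihood(Y: np.ndarray, p: np.ndarray, lam: np.ndarray) -> float:
    """Mixture-of-Bernoulli log-likelihood via explicit loops."""
    total = 0.0
    for i in range(Y.shape[0]):
        mix = 0.0
        for k in range(len(p)):
            f = 1.0
            for j in range(Y.shape[1]):
                f *= lam[k, j] if Y[i, j] == 1 else 1.0 - lam[k, j]
            mix += p[k] * f
        total += np.log(mix)
    return total


def loop_gom_log_likelihood(Y: np.ndarray, gam: np.ndarray, g: np.ndarray) -> float:
    """Grade-of-membership log-likelihood via explicit loops."""
    total = 0.0
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            q = sum(g[i, k] * gam[k, j] for k in range(gam.shape[0]))
            total += np.log(q) if Y[i, j] == 1 else np.log(1.0 - q)
    return total


def lca_exact_posterior(Y: np.ndarray, K: int = 2):
    """Exact LCA posterior over class assignments by enumeration.

    With priors p ~ Dirichlet(1,..,1) and lambda_kj ~ Beta(1,1), the joint
    p(Y, z) integrates in closed form:
        p(z) = Gamma(K) * prod_k Gamma(n_k + 1) / Gamma(n + K)
        p(Y|z) = prod_{k,j} B(a_kj + 1, n_k - a_kj + 1)
    Returns (mean_z: (n, K) posterior membership, co: (n, n) P(z_i = z_j)).
    """
    n, J = Y.shape
    log_probs = []
    assignments = list(product(range(K), repeat=n))
    for z in assignments:
        z = np.asarray(z)
        counts = np.bincount(z, minlength=K)
        lp = gammaln(K) + gammaln(counts + 1).sum() - gammaln(n + K)
        for k in range(K):
            rows = Y[z == k]
            a = rows.sum(axis=0) if len(rows) else np.zeros(J)
            lp += betaln(a + 1, counts[k] - a + 1).sum()
        log_probs.append(lp)
    log_probs = np.asarray(log_probs)
    w = np.exp(log_probs - logsumexp(log_probs))
    mean_z = np.zeros((n, K))
    co = np.zeros((n, n))
    for wz, z in zip(w, assignments):
        z = np.asarray(z)
        mean_z[np.arange(n), z] += wz
        co += wz * (z[:, None] == z[None, :])
    return mean_z, co


def gom_exact_posterior(Y: np.ndarray, K: int = 2):
    """Exact GoM posterior by enumerating all K^(nJ) omega configurations.

    With g_i ~ Dirichlet(1,..,1) and gamma_kj ~ Beta(1,1):
        p(omega_i) = Gamma(K) * prod_k Gamma(c_ik + 1) / Gamma(J + K)
        p(Y|omega) = prod_{k,j} B(a_kj + 1, b_kj + 1)
        E[g_ik | omega] = (c_ik + 1) / (J + K)
    Returns (mean_g: (n, K), co: (n, n) E[sum_k g_ik g_jk] with the diagonal
    left as E[sum_k E(g_ik|omega)^2], matching product-of-means estimators).
    """
    n, J = Y.shape
    configs = list(product(range(K), repeat=n * J))
    log_probs = []
    cond_means = []
    for flat in configs:
        om = np.asarray(flat).reshape(n, J)
        counts = np.stack([np.bincount(om[i], minlength=K) for i in range(n)])  # (n, K)
        lp = n * gammaln(K) - n * gammaln(J + K) + gammaln(counts + 1).sum()
        a = np.zeros((K, J))
        b = np.zeros((K, J))
        for k in range(K):
            mask = om == k
            a[k] = (mask * Y).sum(axis=0)
            b[k] = (mask * (1 - Y)).sum(axis=0)
        lp += betaln(a + 1, b + 1).sum()
        log_probs.append(lp)
        cond_means.append((counts + 1) / (J + K))
    log_probs = np.asarray(log_probs)
    w = np.exp(log_probs - logsumexp(log_probs))
    cond_means = np.asarray(cond_means)  # (C, n, K)
    mean_g = np.einsum("c,cnk->nk", w, cond_means)
    co = np.einsum("c,cik,cjk->ij", w, cond_means, cond_means)
    return mean_g, co


def gaussian_conjugate_log_evidence(x: np.ndarray, sigma: float, prior_sd: float) -> float:
    """Exact log marginal likelihood of N(mu, sigma^2) data with mu ~ N(0, prior_sd^2).

    Marginally x ~ N(0, sigma^2 I + prior_sd^2 11'); evaluated via the
    standard decomposition in terms of the sample mean.
    """
    n = len(x)
    s2, t2 = sigma**2, prior_sd**2
    xbar = x.mean()
    ss = ((x - xbar) ** 2).sum()
    # p(x) = prod N(x_i | 0, ...) factorised: residuals around xbar, then xbar ~ N(0, t2 + s2/n)
    log_lik_resid = -0.5 * (n - 1) * np.log(2 * np.pi * s2) - ss / (2 * s2) - 0.5 * np.log(n)
    var_xbar = t2 + s2 / n
    log_marg_mean = -0.5 * np.log(2 * np.pi * var_xbar) - xbar**2 / (2 * var_xbar)
    return float(log_lik_resid + log_marg_mean)


def match_rows(estimate: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute estimate rows to best match truth rows (L1, optimal assignment)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(estimate[:, None, :] - truth[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return estimate[perm]
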