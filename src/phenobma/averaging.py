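"""Cross-model cluster reconciliation and Bayesian model averaging of traits.

Clusters found by different models carry arbitrary labels and need not
correspond one-to-one. Clusters whose mean symptom prevalence is below an
"unaffected" threshold are excluded; remaining clusters are matched across
models by profile similarity. Matched pairs are merged into a single
phenotypic trait whose per-individual value is the weighted combination

    phi_i = sum_s phi_is * p(M_s | Y)

over the contributing models; clusters with no counterpart remain distinct
and pass their model's phi column through unchanged (their linkage signal
should not be diluted by a model that never found the cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FittedModel, ValidationError
from .evidence import ModelWeights

__all__ = [
    "ClusterCorrespondence",
    "AveragedPhenotypeSet",
    "match_clusters",
    "average_phenotypes",
    "classify",
    "sensitivity_specificity",
]


@dataclass
class ClusterCorrespondence:
    """Cross-model cluster matching decisions.

    Clusters are addressed as (side, index) with side "A" or "B" referring to
    the two profile matrices given to :func:`match_clusters`.
    """

    pairs: list[tuple[int, int, float]]  # (cluster_A, cluster_B, mean abs profile diff)
    merged: list[tuple[int, int, float]]  # subset of pairs with distance <= threshold
    retained_distinct: list[tuple[str, int]]  # (side, cluster) with no merge partner
    excluded_unaffected: list[tuple[str, int]]
    merge_threshold: float
    unaffected_threshold: float


@dataclass
class AveragedPhenotypeSet:
    traits: dict[str, np.ndarray]  # trait name -> per-individual phi in [0, 1]
    provenance: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    individual_ids: tuple[str, ...] = ()


def match_clusters(
    profiles_A: np.ndarray,
    profiles_B: np.ndarray,
    merge_threshold: float = 0.10,
    unaffected_threshold: float = 0.20,
    relevant_symptoms: list[int] | None = None,
) -> ClusterCorrespondence:
    """Reconcile the clusters of two models from their symptom-prevalence profiles.

    A cluster whose mean prevalence over ``relevant_symptoms`` (all symptoms
    by default) is below ``unaffected_threshold`` is flagged unaffected and
    excluded. The remaining A-B cluster pairs are greedily matched in order
    of ascending mean absolute profile difference; a matched pair is merged
    when its distance is at most ``merge_threshold``, otherwise both members
    stay distinct. Unmatched clusters stay distinct.
    """
    A = np.asarray(profiles_A, dtype=float)
    B = np.asarray(profiles_B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValidationError("profile matrices must share the symptom dimension")
    for thr in (merge_threshold, unaffected_threshold):
        if not (0.0 < thr < 1.0):
            raise ValidationError("thresholds must lie in (0, 1)")
    cols = slice(None) if relevant_symptoms is None else list(relevant_symptoms)

    excluded = [("A", int(k)) for k in range(A.shape[0]) if A[k, cols].mean() < unaffected_threshold]
    excluded += [("B", int(k)) for k in range(B.shape[0]) if B[k, cols].mean() < unaffected_threshold]
    live_A = [k for k in range(A.shape[0]) if ("A", k) not in excluded]
    live_B = [k for k in range(B.shape[0]) if ("B", k) not in excluded]

    candidates = sorted(
        ((float(np.abs(A[a] - B[b]).mean()), a, b) for a in live_A for b in live_B)
    )
    pairs: list[tuple[int, int, float]] = []
    merged: list[tuple[int, int, float]] = []
    used_A: set[int] = set()
    used_B: set[int] = set()
    for dist, a, b in candidates:
        if a in used_A or b in used_B:
            continue
        used_A.add(a)
        used_B.add(b)
        pairs.append((a, b, dist))
        if dist <= merge_threshold:
            merged.append((a, b, dist))
    merged_A = {a for a, _, _ in merged}
    merged_B = {b for _, b, _ in merged}
    retained = [("A", a) for a in live_A if a not in merged_A]
    retained += [("B", b) for b in live_B if b not in merged_B]
    return ClusterCorrespondence(
        pairs=pairs,
        merged=merged,
        retained_distinct=retained,
        excluded_unaffected=excluded,
        merge_threshold=merge_threshold,
        unaffected_threshold=unaffected_threshold,
    )


def average_phenotypes(
    fits: list[FittedModel],
    corr: ClusterCorrespondence,
    weights: ModelWeights,
) -> AveragedPhenotypeSet:
    """Build per-individual phenotypic traits from the reconciled clusters.

    ``fits`` must be the [A, B] pair the correspondence was computed from,
    covering identical individuals in identical order. Merged traits use the
    model-averaged phi (weights renormalised over the contributing models);
    retained-distinct traits pass the source model's phi column through
    unchanged. Excluded clusters produce no trait. Traits are named K1, K2,
    ... in order of decreasing mean profile prevalence.
    """
    if len(fits) != 2:
        raise ValidationError("averaging requires exactly two fitted models (A and B)")
    fit_A, fit_B = fits
    if fit_A.individual_ids != fit_B.individual_ids:
        raise ValidationError("fits must cover identical individuals in identical order")
    w = np.asarray(weights.weights, dtype=float)

    entries = []  # (mean prevalence, phi vector, provenance)
    for a, b, dist in corr.merged:
        wa, wb = w[0] / (w[0] + w[1]), w[1] / (w[0] + w[1])
        phi = wa * fit_A.phi[:, a] + wb * fit_B.phi[:, b]
        prev = float((wa * fit_A.profiles[a] + wb * fit_B.profiles[b]).mean())
        entries.append((prev, phi, [("A", a, float(wa)), ("B", b, float(wb))]))
    for side, k in corr.retained_distinct:
        fit = fit_A if side == "A" else fit_B
        entries.append((float(fit.profiles[k].mean()), fit.phi[:, k].copy(), [(side, k, 1.0)]))

    entries.sort(key=lambda e: -e[0])
    traits = {}
    provenance = {}
    for i, (_, phi, prov) in enumerate(entries):
        name = f"K{i + 1}"
        traits[name] = np.clip(phi, 0.0, 1.0)
        provenance[name] = prov
    return AveragedPhenotypeSet(traits=traits, provenance=provenance, individual_ids=fit_A.individual_ids)


def classify(trait: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary affection labels: 1 iff phi >= threshold (ties count as affected)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    phi = np.asarray(trait, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValidationError("trait values must lie in [0, 1]")
    return (phi >= threshold).astype(int)


def sensitivity_specificity(labels: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) of binary labels."""
    labels = np.asarray(labels).astype(int)
    truth = np.asarray(truth).astype(int)
    if labels.shape != truth.shape:
        raise ValidationError("labels and truth must have the same length")
    if truth.sum() == 0 or truth.sum() == truth.size:
        raise ValidationError("truth must contain at least one positive and one negative")
    tp = int(((labels == 1) & (truth == 1)).sum())
    fn = int(((labels == 0) & (truth == 1)).sum())
    tn = int(((labels == 0) & (truth == 0)).sum())
    fp = int(((labels == 1) & (truth == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)
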