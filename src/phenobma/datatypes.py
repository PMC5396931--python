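"""Core data containers shared across the phenotype-averaging pipeline.

The pipeline operates on binary symptom matrices (individuals x symptoms),
fitted mixture-model summaries, and nuclear-family pedigrees with
microsatellite genotypes and a genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhenotypeScheme",
    "SymptomMatrix",
    "FittedModel",
    "Family",
    "PedigreeData",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# Default symptom universe: twelve clinical items a..l, of which only b..h are
# disease-relevant; a, i, j, k, l are background noise symptoms included to
# test whether the clustering can ignore irrelevant items.
DEFAULT_SYMPTOMS = tuple("abcdefghijkl")

# Affected sub-type symptom sets (by label). P3 contains every symptom of P2,
# and P2 nearly every symptom of P1, so the sub-types overlap heavily.
P1_SYMPTOMS = frozenset("befh")
P2_SYMPTOMS = frozenset("cdefgh")
P3_SYMPTOMS = frozenset("bcdefgh")


@dataclass(frozen=True)
class PhenotypeScheme:
    """Generative description of a population of phenotype classes.

    Each class k is characterised by a subset of symptoms expressed with
    probability ``penetrance_in``; all other symptoms appear with the
    background probability ``penetrance_out``. A class with an empty symptom
    set is "unaffected" (all symptoms at background rate).
    """

    symptom_labels: tuple[str, ...]
    class_names: tuple[str, ...]
    class_symptom_sets: tuple[frozenset[int], ...]
    class_proportions: tuple[float, ...]
    penetrance_in: float = 0.9
    penetrance_out: float = 0.05

    def __post_init__(self) -> None:
        J = len(self.symptom_labels)
        props = np.asarray(self.class_proportions, dtype=float)
        if len(self.class_symptom_sets) != len(props) or len(self.class_names) != len(props):
            raise ValidationError("class_names, class_symptom_sets and class_proportions must align")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ValidationError("class_proportions must be a simplex (sum 1 +/- 1e-12)")
        for s in self.class_symptom_sets:
            if any(j < 0 or j >= J for j in s):
                raise ValidationError("class symptom sets must index into symptom_labels")
        if not (0.0 <= self.penetrance_out < self.penetrance_in <= 1.0):
            raise ValidationError("require 0 <= penetrance_out < penetrance_in <= 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_symptom_sets)

    @property
    def n_symptoms(self) -> int:
        return len(self.symptom_labels)

    def symptom_probabilities(self) -> np.ndarray:
        """Per-class Bernoulli rates implied by the penetrances, shape (K, J)."""
        K, J = self.n_classes, self.n_symptoms
        lam = np.full((K, J), self.penetrance_out, dtype=float)
        for k, symset in enumerate(self.class_symptom_sets):
            lam[k, sorted(symset)] = self.penetrance_in
        return lam

    @classmethod
    def from_labels(
        cls,
        class_defs: Sequence[tuple[str, frozenset[str]]],
        class_proportions: Sequence[float],
        symptom_labels: Sequence[str] = DEFAULT_SYMPTOMS,
        penetrance_in: float = 0.9,
        penetrance_out: float = 0.05,
    ) -> "PhenotypeScheme":
        idx = {s: j for j, s in enumerate(symptom_labels)}
        sets = tuple(frozenset(idx[s] for s in symset) for _, symset in class_defs)
        return cls(
            symptom_labels=tuple(symptom_labels),
            class_names=tuple(name for name, _ in class_defs),
            class_symptom_sets=sets,
            class_proportions=tuple(np.asarray(class_proportions, float) / np.sum(class_proportions)),
            penetrance_in=penetrance_in,
            penetrance_out=penetrance_out,
        )

    @classmethod
    def kpd_default(cls, penetrance_in: float = 0.9, penetrance_out: float = 0.05) -> "PhenotypeScheme":
        """Four-class KPD-like scheme: P1, P2, P3 and unaffected.

        Class counts follow the published population composition
        (184, 193, 178, 853 out of 1408).
        """
        return cls.from_labels(
            [("P1", P1_SYMPTOMS), ("P2", P2_SYMPTOMS), ("P3", P3_SYMPTOMS), ("unaffected", frozenset())],
            [184, 193, 178, 853],
            penetrance_in=penetrance_in,
            penetrance_out=penetrance_out,
        )

    @classmethod
    def three_class(cls, penetrance_in: float = 0.9, penetrance_out: float = 0.05) -> "PhenotypeScheme":
        """Separable three-class scheme (P1, P3, unaffected).

        Drops P2, whose symptom set is nearly contained in P3 and which the
        clustering models cannot reliably distinguish; class counts keep the
        relative frequencies of the remaining classes.
        """
        return cls.from_labels(
            [("P1", P1_SYMPTOMS), ("P3", P3_SYMPTOMS), ("unaffected", frozenset())],
            [184, 178, 853],
            penetrance_in=penetrance_in,
            penetrance_out=penetrance_out,
        )


@dataclass(frozen=True)
class SymptomMatrix:
    """n x J binary responses with individual and symptom labels."""

    individual_ids: tuple[str, ...]
    symptom_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape != (len(self.individual_ids), len(self.symptom_labels)):
            raise ValidationError("values must be an (n_individuals, n_symptoms) matrix")
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("symptom values must all be 0 or 1 (no missing data)")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("individual ids must be unique")
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def J(self) -> int:
        return len(self.symptom_labels)


@dataclass
class FittedModel:
    """Posterior summary of one clustering model fit by Gibbs sampling.

    ``phi`` holds the per-individual membership probabilities (the posterior
    mean of delta_ik for LCA, of g_ik for GoM) over post-burn-in draws after
    relabelling; ``retained`` keeps the relabelled parameter draws needed for
    the Laplace-Gibbs evidence.
    """

    model_tag: str  # "LCA" or "GoM"
    K: int
    individual_ids: tuple[str, ...]
    symptom_labels: tuple[str, ...]
    profiles: np.ndarray  # (K, J) posterior-mean symptom prevalence
    phi: np.ndarray  # (n, K) membership probabilities
    deviance_trace: np.ndarray  # (n_chains, n_iter)
    retained: dict[str, np.ndarray]  # pooled relabelled draws
    max_log_likelihood: float
    bic: float | None = None
    log_marginal_likelihood: float | None = None
    settings: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def J(self) -> int:
        return len(self.symptom_labels)


@dataclass(frozen=True)
class Family:
    family_id: str
    father_id: str
    mother_id: str
    offspring_ids: tuple[str, ...]


@dataclass
class PedigreeData:
    """Nuclear families with genotypes at M ordered markers and a trait.

    Genotypes are unordered allele pairs of positive integers (0 = missing);
    ``map_cM`` gives strictly increasing marker positions in centimorgans.
    """

    families: list[Family]
    genotypes: dict[str, np.ndarray]  # individual id -> (M, 2) int array
    marker_names: tuple[str, ...]
    map_cM: np.ndarray
    chromosomes: tuple[int, ...]
    trait: dict[str, float]
    sex: dict[str, int]

    def __post_init__(self) -> None:
        self.map_cM = np.asarray(self.map_cM, dtype=float)
        if len(self.marker_names) != len(self.map_cM) or len(self.chromosomes) != len(self.map_cM):
            raise ValidationError("marker_names, chromosomes and map_cM must align")
        for c in np.unique(self.chromosomes):
            pos = self.map_cM[np.asarray(self.chromosomes) == c]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("map positions must be strictly increasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)
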