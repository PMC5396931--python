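"""Synthetic KPD-like data: symptom matrices and nuclear-family pedigrees.

The original study population is restricted, so every downstream stage is
exercised on data generated here. Two symptom generators are provided: a
crisp-class generator (each individual belongs to exactly one phenotype
class, the latent-class data-generating law) and a mixed-membership
generator (each individual has a Dirichlet-distributed membership vector,
the grade-of-membership law). The pedigree generator produces nuclear
families typed at evenly spaced microsatellite markers with a biallelic
liability locus co-segregating with one marker.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    Family,
    PedigreeData,
    PhenotypeScheme,
    SymptomMatrix,
    ValidationError,
)

__all__ = [
    "simulate_symptoms",
    "simulate_mixed_membership",
    "simulate_pedigrees",
    "haldane_recombination_fraction",
    "mendelian_errors",
]


def haldane_recombination_fraction(d_cM: float) -> float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _symptoms_for_labels(scheme: PhenotypeScheme, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lam = scheme.symptom_probabilities()  # (K, J)
    probs = lam[labels]  # (n, J)
    return (rng.random(probs.shape) < probs).astype(np.int8)


def _ids(n: int, prefix: str = "ind") -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def simulate_symptoms(
    scheme: PhenotypeScheme, n: int, seed: int
) -> tuple[SymptomMatrix, np.ndarray]:
    """Draw n individuals with crisp class labels and Bernoulli symptoms.

    Individual i's class is drawn from ``scheme.class_proportions``; symptom j
    is present with probability ``penetrance_in`` if j belongs to the class
    symptom set and ``penetrance_out`` otherwise.

    Returns the symptom matrix and the true class index per individual.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(scheme.n_classes, size=n, p=np.asarray(scheme.class_proportions))
    values = _symptoms_for_labels(scheme, labels, rng)
    sm = SymptomMatrix(_ids(n), tuple(scheme.symptom_labels), values)
    return sm, labels


def simulate_mixed_membership(
    scheme: PhenotypeScheme, n: int, concentration: float, seed: int
) -> tuple[SymptomMatrix, np.ndarray]:
    """Draw mixed-membership data: the grade-of-membership generative law.

    Membership rows g_i are symmetric Dirichlet(concentration) over the K
    classes; symptom j of individual i is present with probability
    sum_k g_ik * lambda_kj, where lambda is the class symptom-rate matrix
    implied by the scheme penetrances.

    Returns the symptom matrix and the true n x K membership rows.
    """
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K = scheme.n_classes
    g = rng.dirichlet(np.full(K, concentration), size=n)
    lam = scheme.symptom_probabilities()
    probs = g @ lam
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    sm = SymptomMatrix(_ids(n), tuple(scheme.symptom_labels), values)
    return sm, g


def _gamete(
    rng: np.random.Generator,
    genotype: np.ndarray,
    risk: np.ndarray,
    qtl_marker: int,
    rec: np.ndarray,
) -> tuple[np.ndarray, int]:
    """One recombinant gamete: marker alleles plus the transmitted risk allele.

    ``genotype`` is (M, 2) with columns as the parent's two haplotypes; the
    risk allele rides on the haplotype present at the liability-locus marker.
    """
    M = genotype.shape[0]
    hap = np.empty(M, dtype=np.int64)
    hap[0] = rng.integers(2)
    if M > 1:
        switches = rng.random(M - 1) < rec
        hap[1:] = (hap[0] + np.cumsum(switches)) % 2
    alleles = genotype[np.arange(M), hap]
    return alleles, int(risk[hap[qtl_marker]])


def simulate_pedigrees(
    n_families: int,
    offspring_per_family: int,
    n_markers: int,
    spacing_cM: float = 7.5,
    qtl_marker: int = 0,
    qtl_effect: float = 2.0,
    scheme: PhenotypeScheme | None = None,
    seed: int = 0,
    liability_threshold: float = 2.0,
    severity_gap: float = 1.0,
    risk_allele_freq: float = 0.5,
    chromosome: int = 1,
) -> tuple[PedigreeData, SymptomMatrix, np.ndarray]:
    """Simulate nuclear families with markers, a liability locus and symptoms.

    Founders carry four distinct marker alleles per family (fully informative
    markers, so single-point IBD in offspring is exact). Gametes recombine
    between adjacent markers with the Haldane fraction for ``spacing_cM``.
    A biallelic liability locus co-segregates with marker ``qtl_marker``
    (0-based): each founder haplotype carries a risk allele with probability
    ``risk_allele_freq``, and an offspring's liability is
    ``qtl_effect * (number of risk alleles) + N(0, 1)``. Affection follows a
    graded liability-threshold model: offspring below ``liability_threshold``
    are unaffected; affected classes, ordered by severity (symptom-set
    size), occupy successive liability bands of width ``severity_gap``, so
    higher liability yields the more severe sub-type. Symptoms follow the
    same penetrance law as :func:`simulate_symptoms`. The pedigree trait
    records the continuous liability for offspring (0.0 for founders);
    phenotype-probability traits for linkage are supplied downstream.

    Returns the pedigree, the offspring symptom matrix, and true class labels
    aligned with the symptom-matrix rows.
    """
    if scheme is None:
        scheme = PhenotypeScheme.three_class()
    if not (0 <= qtl_marker < n_markers):
        raise IndexError("qtl_marker must lie in [0, n_markers)")
    if spacing_cM <= 0:
        raise ValidationError("spacing_cM must be positive")
    if offspring_per_family < 2:
        raise ValidationError("each family needs at least two offspring for sib pairs")

    rng = np.random.default_rng(seed)
    r = haldane_recombination_fraction(spacing_cM)
    rec = np.full(max(n_markers - 1, 0), r)

    # affected classes in ascending severity (number of class symptoms)
    affected_classes = sorted(
        (k for k, s in enumerate(scheme.class_symptom_sets) if len(s) > 0),
        key=lambda k: len(scheme.class_symptom_sets[k]),
    )
    unaffected_classes = [k for k, s in enumerate(scheme.class_symptom_sets) if len(s) == 0]
    if not affected_classes or not unaffected_classes:
        raise ValidationError("scheme must contain at least one affected and one unaffected class")
    # liability band edges: [threshold, threshold + gap, ...); the top band is open
    band_edges = liability_threshold + severity_gap * np.arange(len(affected_classes))

    families: list[Family] = []
    genotypes: dict[str, np.ndarray] = {}
    trait: dict[str, float] = {}
    sex: dict[str, int] = {}
    offspring_ids: list[str] = []
    labels: list[int] = []

    for f in range(n_families):
        fam = f"F{f + 1:04d}"
        father, mother = f"{fam}_1", f"{fam}_2"
        base = 4 * f
        # four distinct founder alleles per family at every marker
        gt_father = np.tile([base + 1, base + 2], (n_markers, 1))
        gt_mother = np.tile([base + 3, base + 4], (n_markers, 1))
        risk_father = (rng.random(2) < risk_allele_freq).astype(int)
        risk_mother = (rng.random(2) < risk_allele_freq).astype(int)
        genotypes[father] = gt_father
        genotypes[mother] = gt_mother
        trait[father] = 0.0
        trait[mother] = 0.0
        sex[father], sex[mother] = 1, 2
        kids = []
        for c in range(offspring_per_family):
            kid = f"{fam}_{c + 3}"
            pat, pat_risk = _gamete(rng, gt_father, risk_father, qtl_marker, rec)
            mat, mat_risk = _gamete(rng, gt_mother, risk_mother, qtl_marker, rec)
            genotypes[kid] = np.column_stack([pat, mat])
            liability = qtl_effect * (pat_risk + mat_risk) + rng.normal()
            if liability >= liability_threshold:
                band = int((liability >= band_edges).sum()) - 1
                label = affected_classes[band]
            else:
                label = int(rng.choice(unaffected_classes))
            labels.append(label)
            offspring_ids.append(kid)
            trait[kid] = float(liability)
            sex[kid] = 1 + (c % 2)
            kids.append(kid)
        families.append(Family(fam, father, mother, tuple(kids)))

    labels_arr = np.asarray(labels)
    values = _symptoms_for_labels(scheme, labels_arr, rng)
    sm = SymptomMatrix(tuple(offspring_ids), tuple(scheme.symptom_labels), values)
    ped = PedigreeData(
        families=families,
        genotypes=genotypes,
        marker_names=tuple(f"M{m + 1:02d}" for m in range(n_markers)),
        map_cM=np.arange(n_markers) * spacing_cM,
        chromosomes=tuple([chromosome] * n_markers),
        trait=trait,
        sex=sex,
    )
    return ped, sm, labels_arr


def mendelian_errors(ped: PedigreeData) -> list[tuple[str, str, int]]:
    """List (family, offspring, marker) triples violating Mendelian transmission.

    An offspring genotype {x, y} is consistent if some ordering has x among
    the father's alleles and y among the mother's. Markers with missing
    parental genotypes (allele 0) are skipped.
    """
    errors = []
    for fam in ped.families:
        gf = ped.genotypes.get(fam.father_id)
        gm = ped.genotypes.get(fam.mother_id)
        if gf is None or gm is None:
            continue
        for kid in fam.offspring_ids:
            gk = ped.genotypes.get(kid)
            if gk is None:
                continue
            for m in range(ped.n_markers):
                f1, f2 = gf[m]
                m1, m2 = gm[m]
                if 0 in (f1, f2, m1, m2):
                    continue
                a, b = gk[m]
                ok = (a in (f1, f2) and b in (m1, m2)) or (b in (f1, f2) and a in (m1, m2))
                if not ok:
                    errors.append((fam.family_id, kid, m))
    return errors
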