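"""Single-point Haseman-Elston sib-pair linkage scan.

For every sib pair, the squared difference of the quantitative trait is
regressed on the proportion of alleles shared identical by descent (IBD) at
each marker. Under linkage, pairs sharing more alleles have more similar
traits, so the regression slope is negative; the evidence is summarised as
LOD = t^2 / (2 ln 10) for the one-sided test of a negative slope (0 when
the fitted slope is non-negative).

IBD sharing is computed exactly by tracing parental origin, which requires
fully informative markers (four distinct parental alleles); families that
are uninformative at a marker are skipped with a warning. All sib pairs
within a sibship are used, without weighting for their non-independence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import PedigreeData, ValidationError

__all__ = [
    "SibPairObservation",
    "HEResult",
    "estimate_ibd",
    "haseman_elston",
    "genome_scan",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class DegenerateDesignError(ValidationError):
    """Raised when the regression design carries no IBD variation."""


@dataclass(frozen=True)
class SibPairObservation:
    family_id: str
    pair: tuple[str, str]
    squared_trait_difference: float
    pi_hat: float


@dataclass(frozen=True)
class HEResult:
    slope: float
    intercept: float
    se: float
    t: float
    lod: float
    n_pairs: int


def estimate_ibd(
    father_genotype: np.ndarray,
    mother_genotype: np.ndarray,
    sib_genotypes: np.ndarray,
) -> np.ndarray | None:
    """Exact pairwise IBD sharing at one marker for one sibship.

    Requires a fully informative marker: the four parental alleles must be
    distinct, so each sib allele traces uniquely to one parental allele.
    Returns the (s, s) matrix of pi_hat in {0, 0.5, 1}, or None when the
    marker is uninformative in this family.
    """
    father = tuple(int(a) for a in father_genotype)
    mother = tuple(int(a) for a in mother_genotype)
    alleles = set(father) | set(mother)
    if 0 in alleles or len(alleles) != 4:
        return None
    sibs = np.asarray(sib_genotypes)
    origins = []
    for a, b in sibs:
        if a in father and b in mother:
            origins.append((int(a), int(b)))
        elif b in father and a in mother:
            origins.append((int(b), int(a)))
        else:
            return None  # Mendelian inconsistency; treat as uninformative
    s = len(origins)
    pi = np.empty((s, s))
    for i in range(s):
        for j in range(s):
            shared = (origins[i][0] == origins[j][0]) + (origins[i][1] == origins[j][1])
            pi[i, j] = shared / 2.0
    return pi


def haseman_elston(pairs: list[SibPairObservation]) -> HEResult:
    """OLS of squared trait differences on IBD sharing; one-sided LOD.

    Requires at least three pairs and at least two distinct pi_hat values.
    """
    if len(pairs) < 3:
        raise ValidationError("need at least 3 sib pairs")
    x = np.array([p.pi_hat for p in pairs], dtype=float)
    y = np.array([p.squared_trait_difference for p in pairs], dtype=float)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateDesignError("all sib pairs share the same pi_hat; slope undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    dof = len(pairs) - 2
    sigma2 = float((resid**2).sum() / dof)
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        t = -math.inf if slope < 0 else 0.0
    else:
        t = slope / se
    lod = (t * t) / (2.0 * LN10) if slope < 0 else 0.0
    return HEResult(slope=slope, intercept=intercept, se=se, t=t, lod=lod, n_pairs=len(pairs))


def genome_scan(ped: PedigreeData, trait: dict[str, float]) -> pd.DataFrame:
    """Haseman-Elston scan at every marker; returns one row per marker.

    ``trait`` maps offspring ids to quantitative trait values (a continuous
    phenotype probability works exactly like a binary status here). Columns:
    marker, chrom, cM, n_pairs, slope, se, t, lod.
    """
    sibships = []
    for fam in ped.families:
        kids = [k for k in fam.offspring_ids if k in trait]
        if len(kids) >= 2:
            sibships.append((fam, kids))
    if not sibships:
        raise ValidationError("no sibship with >= 2 trait-bearing offspring")

    rows = []
    skipped: set[tuple[str, int]] = set()
    for m, name in enumerate(ped.marker_names):
        obs: list[SibPairObservation] = []
        for fam, kids in sibships:
            pi = estimate_ibd(
                ped.genotypes[fam.father_id][m],
                ped.genotypes[fam.mother_id][m],
                np.array([ped.genotypes[k][m] for k in kids]),
            )
            if pi is None:
                if (fam.family_id, m) not in skipped:
                    skipped.add((fam.family_id, m))
                    logger.warning("marker %s uninformative in family %s; pairs skipped", name, fam.family_id)
                continue
            for i, j in combinations(range(len(kids)), 2):
                obs.append(
                    SibPairObservation(
                        family_id=fam.family_id,
                        pair=(kids[i], kids[j]),
                        squared_trait_difference=(trait[kids[i]] - trait[kids[j]]) ** 2,
                        pi_hat=float(pi[i, j]),
                    )
                )
        if not obs:
            raise ValidationError(f"no usable sib pairs at marker {name}")
        try:
            res = haseman_elston(obs)
        except DegenerateDesignError:
            res = HEResult(slope=0.0, intercept=0.0, se=float("nan"), t=0.0, lod=0.0, n_pairs=len(obs))
        rows.append(
            {
                "marker": name,
                "chrom": ped.chromosomes[m],
                "cM": float(ped.map_cM[m]),
                "n_pairs": res.n_pairs,
                "slope": res.slope,
                "se": res.se,
                "t": res.t,
                "lod": res.lod,
            }
        )
    return pd.DataFrame(rows)
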