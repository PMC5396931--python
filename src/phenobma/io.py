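"""Readers and writers for the pipeline's file formats.

Symptom matrices, membership probabilities and averaged traits travel as
CSV keyed by individual id; pedigrees as LINKAGE pre-makeped PED files with
a 3-column genetic map (chromosome, marker name, cM); linkage results as
TSV; weights, evidence and provenance as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import Family, PedigreeData, SymptomMatrix, ValidationError
from .synthetic import mendelian_errors

__all__ = [
    "read_symptom_csv",
    "write_symptom_csv",
    "write_phi_csv",
    "read_traits_csv",
    "write_traits_csv",
    "read_ped_and_map",
    "write_ped_and_map",
    "write_json",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)


def read_symptom_csv(path) -> SymptomMatrix:
    """Read a symptom matrix CSV: first column individual id, one column per symptom."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate individual ids")
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-binary value {vals[i, j]!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return SymptomMatrix(tuple(str(i) for i in df.index), tuple(str(c) for c in df.columns), vals)


def write_symptom_csv(sm: SymptomMatrix, path) -> None:
    df = pd.DataFrame(sm.values, index=list(sm.individual_ids), columns=list(sm.symptom_labels))
    df.to_csv(path, index_label="individual_id")


def write_phi_csv(fit, path) -> None:
    """Per-individual membership probabilities, one column per cluster."""
    cols = [f"{fit.model_tag}_cluster{k + 1}" for k in range(fit.K)]
    pd.DataFrame(fit.phi, index=list(fit.individual_ids), columns=cols).to_csv(
        path, index_label="individual_id"
    )


def write_traits_csv(traits: dict[str, np.ndarray], individual_ids, path) -> None:
    pd.DataFrame(traits, index=list(individual_ids)).to_csv(path, index_label="individual_id")


def read_traits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_ped_and_map(ped: PedigreeData, ped_path, map_path) -> None:
    """Write LINKAGE pre-makeped PED and a 3-column map file.

    PED columns: FamID IndID FatherID MotherID Sex Trait then two allele
    columns per marker; founders' parents are coded 0.
    """
    with open(ped_path, "w") as fh:
        for fam in ped.families:
            members = [(fam.father_id, "0", "0"), (fam.mother_id, "0", "0")] + [
                (kid, fam.father_id, fam.mother_id) for kid in fam.offspring_ids
            ]
            for ind, fa, mo in members:
                gt = ped.genotypes[ind]
                fields = [
                    fam.family_id,
                    ind,
                    fa,
                    mo,
                    str(ped.sex.get(ind, 0)),
                    f"{ped.trait.get(ind, 0.0):.6g}",
                ]
                fields += [str(int(a)) for pair in gt for a in pair]
                fh.write(" ".join(fields) + "\n")
    with open(map_path, "w") as fh:
        for chrom, name, pos in zip(ped.chromosomes, ped.marker_names, ped.map_cM):
            fh.write(f"{chrom}\t{name}\t{pos:.6g}\n")


def read_ped_and_map(ped_path, map_path) -> PedigreeData:
    """Read a pre-makeped PED plus map; warns on Mendelian inconsistencies."""
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValidationError(f"{map_path}: expected 3 columns (chrom, name, cM), got {len(parts)}")
            map_rows.append((int(parts[0]), parts[1], float(parts[2])))
    M = len(map_rows)

    genotypes: dict[str, np.ndarray] = {}
    trait: dict[str, float] = {}
    sex: dict[str, int] = {}
    fam_members: dict[str, list[tuple[str, str, str]]] = {}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * M:
                raise ValidationError(
                    f"{ped_path}: row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} columns, expected {6 + 2 * M} for {M} markers"
                )
            famid, ind, fa, mo, sx, tr = parts[:6]
            alleles = np.array(parts[6:], dtype=int).reshape(M, 2)
            genotypes[ind] = alleles
            trait[ind] = float(tr)
            sex[ind] = int(sx)
            fam_members.setdefault(famid, []).append((ind, fa, mo))

    families = []
    for famid, members in fam_members.items():
        founders = [ind for ind, fa, mo in members if fa == "0" and mo == "0"]
        kids = [(ind, fa, mo) for ind, fa, mo in members if fa != "0" or mo != "0"]
        if not kids:
            continue
        father = kids[0][1]
        mother = kids[0][2]
        if father not in founders or mother not in founders:
            raise ValidationError(f"{ped_path}: family {famid} is not a nuclear family with typed parents")
        families.append(Family(famid, father, mother, tuple(ind for ind, _, _ in kids)))

    ped = PedigreeData(
        families=families,
        genotypes=genotypes,
        marker_names=tuple(name for _, name, _ in map_rows),
        map_cM=np.array([pos for _, _, pos in map_rows]),
        chromosomes=tuple(chrom for chrom, _, _ in map_rows),
        trait=trait,
        sex=sex,
    )
    for famid, kid, m in mendelian_errors(ped):
        logger.warning("Mendelian inconsistency: family %s, individual %s, marker %s", famid, kid, ped.marker_names[m])
    return ped


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


@dataclasses.dataclass
class RunConfig:
    """Settings for the end-to-end pipeline; YAML-loadable, CLI flags win."""

    seed: int = 0
    K: int = 3
    n_iter: int = 2000
    burn_in: int = 1000
    thin: int = 2
    n_chains: int = 2
    merge_threshold: float = 0.10
    unaffected_threshold: float = 0.20
    classify_threshold: float = 0.5
    model_priors: tuple[float, float] = (0.5, 0.5)
    # simulation settings for `run-all`
    n_families: int = 200
    offspring_per_family: int = 4
    n_markers: int = 12
    spacing_cM: float = 7.5
    qtl_marker: int = 5
    qtl_effect: float = 2.5

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValidationError("burn_in must be < n_iter")
        for name in ("n_iter", "thin", "n_chains", "K", "n_families", "offspring_per_family", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        priors = np.asarray(self.model_priors, dtype=float)
        if np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-12:
            raise ValidationError("model_priors must be a simplex")


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "model_priors" in data:
        data["model_priors"] = tuple(data["model_priors"])
    return RunConfig(**data)
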