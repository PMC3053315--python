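"""Cohort file I/O, run configuration, and ensemble (de)serialization.

A cohort joins three tables on subject ID: a genotype dosage matrix
(values 0/1/2, TSV or VCF), an expression matrix (continuous, log scale)
and a clinical phenotype table (TJ, SJ, Pain, CRP).  Variables carry a
role (snp / transcript / phenotype) that downstream stages use to
constrain causal ordering: SNPs are always sources.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import yaml

logger = logging.getLogger(__name__)

ENSEMBLE_FORMAT = "netens-ensemble"
ENSEMBLE_VERSION = 1

MISSING_MARKERS = {".", "NA", "nan", ""}

#: canonical clinical phenotype names, in reporting order
PHENOTYPES = ("TJ", "SJ", "Pain", "CRP")


@dataclass(frozen=True)
class Variable:
    """A modeled variable: a SNP dosage, a transcript, or a clinical score.

    SNPs are discrete with levels in {0, 1, 2}; transcripts and (transformed)
    phenotypes are continuous.  ``transform`` records the phenotype transform
    applied before modeling (``logit_count`` with max count ``m``, ``log``,
    or ``none``).
    """

    name: str
    role: str  # snp | transcript | phenotype
    domain: str  # discrete | continuous
    transform: str = "none"  # none | logit_count | log
    transform_m: int | None = None  # max count for logit_count

    def __post_init__(self) -> None:
        if self.role not in ("snp", "transcript", "phenotype"):
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.domain not in ("discrete", "continuous"):
            raise ValueError(f"unknown domain {self.domain!r} for variable {self.name!r}")
        if self.role == "snp" and self.domain != "discrete":
            raise ValueError(f"SNP {self.name!r} must be discrete")
        if self.role != "snp" and self.domain != "continuous":
            raise ValueError(f"{self.role} {self.name!r} must be continuous")


@dataclass
class Cohort:
    """Aligned subjects x variables table with per-variable roles.

    ``data`` is indexed by subject ID with one column per variable; missing
    values are NaN.  Fragment fitting assumes complete data, so rows with
    missing values in the selected variables are dropped (with a logged
    count) by :meth:`drop_incomplete`.
    """

    subjects: list[str]
    variables: list[Variable]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in cohort")
        if len(self.subjects) < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if list(self.data.index) != list(self.subjects):
            raise ValueError("data rows must align with subject list")
        if list(self.data.columns) != names:
            raise ValueError("data columns must align with variable list")

    @property
    def N(self) -> int:
        return len(self.subjects)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def names(self, role: str | None = None) -> list[str]:
        return [v.name for v in self.variables if role is None or v.role == role]

    def subset(self, names: Sequence[str]) -> "Cohort":
        keep = [v for v in self.variables if v.name in set(names)]
        return Cohort(list(self.subjects), keep, self.data[[v.name for v in keep]].copy())

    def drop_incomplete(self) -> "Cohort":
        """Drop subjects with any missing value; fitting assumes complete data."""
        mask = self.data.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("dropping %d subjects with missing values", n_dropped)
        kept = self.data.loc[mask]
        return Cohort(list(kept.index), list(self.variables), kept.copy())


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline, serializable to YAML.

    Defaults follow the published protocol: 1024-member ensembles, 30
    simulation replicates, 10-fold knockdown, 80% annealing overlap,
    p < 0.05 significance, at most 2 parents per vertex.
    """

    max_parents: int = 2
    fragments_per_child: int = 16
    ensemble_size: int = 1024
    n_chains: int = 4
    n_replicates: int = 30
    knockdown_fold: float = 10.0
    overlap_target: float = 0.8
    consensus_threshold: float = 0.025
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.fragments_per_child < 1:
            raise ValueError("fragments_per_child must be >= 1")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.knockdown_fold > 0:
            raise ValueError("knockdown_fold must be positive")
        if not 0 < self.overlap_target < 1:
            raise ValueError("overlap_target must lie in (0, 1)")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort reading


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    """Read a subjects x variables TSV: first column subject ID, header names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{what} table {path} needs a subject column plus variables")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df

def _parse_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        raw = df[col].astype(str).str.strip()
        is_missing = raw.isin(MISSING_MARKERS) | raw.str.lower().eq("nan")
        vals = pd.to_numeric(raw.mask(is_missing), errors="coerce")
        bad = vals.isna() & ~is_missing
        if bad.any():
            first = raw.index[bad][0]
            raise ValueError(
                f"non-numeric {what} value {raw.loc[first]!r} at subject {first!r}, column {col!r}"
            )
        out[col] = vals.astype(float)
    return pd.DataFrame(out, index=df.index)


def read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into a subjects x SNPs dosage matrix (GT field -> 0/1/2).

    Multi-allelic sites are rejected; missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    names: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise ValueError(f"multi-allelic site {rec.ID or rec.POS} not supported")
        name = rec.ID or f"{rec.CHROM}_{rec.POS}"
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = rec.gt_types.astype(float)
        dosage = np.where(g == 3, 2.0, g)
        dosage[g == 2] = np.nan
        names.append(name)
        cols.append(dosage)
    return pd.DataFrame(np.column_stack(cols), index=subjects, columns=names)


def read_cohort(
    genotype_path: str | Path,
    expression_path: str | Path,
    phenotype_path: str | Path,
    snp_chromosomes: Mapping[str, str] | None = None,
) -> Cohort:
    """Join the three cohort tables on the intersection of subject IDs.

    Genotype values outside {0, 1, 2, missing} are fatal and name the SNP.
    ``snp_chromosomes`` optionally maps SNP name -> chromosome for sex-
    chromosome filtering during QC.
    """
    gpath = str(genotype_path)
    if gpath.endswith((".vcf", ".vcf.gz")):
        geno = read_genotypes_vcf(gpath)
    else:
        geno = _parse_numeric(_read_table(gpath, "genotype"), "genotype")
    expr = _parse_numeric(_read_table(expression_path, "expression"), "expression")
    phen = _parse_numeric(_read_table(phenotype_path, "phenotype"), "phenotype")

    for snp in geno.columns:
        vals = geno[snp].dropna().unique()
        bad = [v for v in vals if v not in (0.0, 1.0, 2.0)]
        if bad:
            raise ValueError(f"genotype value {bad[0]!r} for SNP {snp!r} is not in {{0,1,2}}")

    subjects = sorted(set(geno.index) & set(expr.index) & set(phen.index))
    if not subjects:
        raise ValueError("no subjects shared across genotype, expression and phenotype tables")
    if len(subjects) < 2:
        raise ValueError(f"only {len(subjects)} shared subject(s); need at least 2")

    variables = (
        [Variable(n, "snp", "discrete") for n in geno.columns]
        + [Variable(n, "transcript", "continuous") for n in expr.columns]
        + [Variable(n, "phenotype", "continuous") for n in phen.columns]
    )
    data = pd.concat(
        [geno.loc[subjects], expr.loc[subjects], phen.loc[subjects]], axis=1
    )
    cohort = Cohort(subjects, variables, data)
    cohort.snp_chromosomes = dict(snp_chromosomes) if snp_chromosomes else {}  # type: ignore[attr-defined]
    return cohort


# ---------------------------------------------------------------------------
# ensemble serialization (versioned JSON; human-inspectable and diff-able)


def write_ensemble(ensemble, path: str | Path) -> None:
    """Serialize an :class:`~netens.sampler.Ensemble` losslessly to JSON."""
    if not ensemble.members:
        raise ValueError("refusing to serialize an empty ensemble")
    from netens.fragments import fragment_to_dict

    library = {
        child: [fragment_to_dict(f) for f in frags]
        for child, frags in ensemble.library.items()
    }
    doc = {
        "format": ENSEMBLE_FORMAT,
        "version": ENSEMBLE_VERSION,
        "config": ensemble.config.to_dict(),
        "seed": ensemble.seed,
        "schedules": ensemble.schedules,
        "library": library,
        "members": [
            {child: idx for child, idx in member.items()} for member in ensemble.assignments
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_ensemble(path: str | Path):
    """Read an ensemble written by :func:`write_ensemble`."""
    from netens.fragments import fragment_from_dict
    from netens.sampler import Ensemble

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != ENSEMBLE_FORMAT or doc.get("version") != ENSEMBLE_VERSION:
        raise ValueError(
            f"unsupported ensemble file (format={doc.get('format')!r}, "
            f"version={doc.get('version')!r})"
        )
    library = {
        child: [fragment_from_dict(d) for d in frags]
        for child, frags in doc["library"].items()
    }
    return Ensemble(
        library=library,
        assignments=[dict(m) for m in doc["members"]],
        config=RunConfig.from_dict(doc["config"]),
        seed=doc["seed"],
        schedules=doc["schedules"],
    )


# ---------------------------------------------------------------------------
# consensus export


def consensus_edges(ensemble, threshold: float) -> dict[tuple[str, str], float]:
    """Directed edges whose frequency across ensemble members >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    freq = ensemble.edge_frequencies()
    return {e: f for e, f in freq.items() if f >= threshold}


def export_consensus(
    ensemble,
    threshold: float,
    graphml_path: str | Path | None = None,
    dot_path: str | Path | None = None,
) -> nx.DiGraph:
    """Export the consensus topology at ``threshold`` as GraphML and/or DOT.

    Each surviving edge is annotated with its ensemble frequency.
    """
    edges = consensus_edges(ensemble, threshold)
    g = nx.DiGraph()
    for (parent, child), f in sorted(edges.items()):
        g.add_edge(parent, child, frequency=float(f))
    if graphml_path is not None:
        nx.write_graphml(g, str(graphml_path))
    if dot_path is not None:
        lines = ["digraph consensus {"]
        for (parent, child), f in sorted(edges.items()):
            lines.append(f'  "{parent}" -> "{child}" [label="{f:.3f}"];')
        lines.append("}")
        Path(dot_path).write_text("\n".join(lines) + "\n")
    return g
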