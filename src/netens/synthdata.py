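"""Synthetic cohorts with known causal ground truth.

The generator emulates the assumed data-generating process of the real
study: SNPs in Hardy-Weinberg equilibrium at specified minor-allele
frequencies, cis-eQTL effects anchoring a sparse linear-Gaussian
transcript cascade on the natural-log expression scale, and a small set
of "planted" causal transcripts driving latent clinical scores that are
squashed to the bounded clinical scales (inverse-logit to 0-28 joint
counts and the 0-100 Pain VAS; exponential to CRP in mg/L).  Because the
bounded phenotypes are produced by inverse-logit squashing of a Gaussian
latent, the pipeline's logit transform is the correct inverse and the
modeling assumptions hold by construction; a heavy-tailed noise switch
produces deliberately misspecified data for robustness checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from netens.cohort_io import PHENOTYPES, Cohort, Variable
from netens.fragments import Fragment, StateParams
from netens.sampler import NetworkModel, topological_order


@dataclass
class GroundTruth:
    """A known causal DAG over SNPs, transcripts and latent phenotypes."""

    snps: list[str]
    transcripts: list[str]
    phenotypes: list[str]
    mafs: dict[str, float]
    parents: dict[str, list[tuple[str, float]]]  # child -> [(parent, coefficient)]
    noise_sd: dict[str, float]
    planted: dict[str, list[str]]  # transcript -> phenotypes it drives
    heavy_tails: bool = False

    def __post_init__(self) -> None:
        order = topological_order(self.nodes(), self.edges())
        if order is None:
            raise ValueError("ground-truth graph has a cycle")
        self._order = order

    def nodes(self) -> list[str]:
        return [*self.snps, *self.transcripts, *self.phenotypes]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in self.parents.items() for p, _ in ps]

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc.pop("_order", None)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        doc["parents"] = {
            c: [(p, float(b)) for p, b in ps] for c, ps in doc["parents"].items()
        }
        return cls(**doc)


def generate_ground_truth(
    n_snps: int = 20,
    n_genes: int = 30,
    n_planted: int = 3,
    p_eqtl: float = 0.8,
    p_cascade: float = 0.3,
    effect_size_range: tuple[float, float] = (0.6, 1.2),
    maf_range: tuple[float, float] = (0.15, 0.5),
    transcript_sd: float = 0.5,
    phenotype_sd: float = 0.4,
    rng: np.random.Generator | None = None,
    heavy_tails: bool = False,
) -> GroundTruth:
    """Random DAG respecting the causal ordering SNP -> transcript -> phenotype.

    Each transcript gets a cis-eQTL SNP parent with probability ``p_eqtl``
    and at most one upstream-transcript parent with probability
    ``p_cascade``; the first ``n_planted`` transcripts (in a random order)
    are wired into the phenotype latents, cycling over TJ, SJ, Pain, CRP so
    every phenotype has at least one planted cause when n_planted >= 4 (and
    the composite DAS28 always has several).
    """
    if n_snps < 1 or n_genes < 1:
        raise ValueError("need at least one SNP and one transcript")
    if n_planted > n_genes:
        raise ValueError("cannot plant more causes than transcripts")
    rng = np.random.default_rng(rng)
    snps = [f"rs{i:04d}" for i in range(n_snps)]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    phens = list(PHENOTYPES)

    lo, hi = effect_size_range

    def coef() -> float:
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    mafs = {s: float(rng.uniform(*maf_range)) for s in snps}
    parents: dict[str, list[tuple[str, float]]] = {}
    noise_sd: dict[str, float] = {}
    for j, g in enumerate(genes):
        ps: list[tuple[str, float]] = []
        if rng.random() < p_eqtl:
            ps.append((snps[int(rng.integers(n_snps))], coef()))
        if j > 0 and rng.random() < p_cascade:
            ps.append((genes[int(rng.integers(j))], coef()))
        parents[g] = ps
        noise_sd[g] = transcript_sd

    chosen = [genes[i] for i in rng.choice(n_genes, size=n_planted, replace=False)]
    # planted causes are always cis-eQTL-anchored: genetic anchoring is what
    # lets the framework orient transcript -> phenotype edges causally
    for g in chosen:
        if not any(p in mafs for p, _ in parents[g]):
            parents[g] = [(snps[int(rng.integers(n_snps))], coef()), *parents[g]]
    planted: dict[str, list[str]] = {g: [] for g in chosen}
    phen_parents: dict[str, list[tuple[str, float]]] = {p: [] for p in phens}
    for i, g in enumerate(chosen):
        ph = phens[i % len(phens)]
        # strong positive planted effects so knockdowns reduce disease scores
        phen_parents[ph].append((g, float(rng.uniform(0.8, 1.2))))
        planted[g].append(ph)
    for p in phens:
        parents[p] = phen_parents[p]
        noise_sd[p] = phenotype_sd
    return GroundTruth(
        snps=snps,
        transcripts=genes,
        phenotypes=phens,
        mafs=mafs,
        parents=parents,
        noise_sd=noise_sd,
        planted=planted,
        heavy_tails=heavy_tails,
    )


def generate_cohort(
    gt: GroundTruth, n_subjects: int = 100, rng: np.random.Generator | None = None
) -> Cohort:
    """Ancestral simulation of the ground truth into a clinical-scale cohort.

    SNP dosages are Binomial(2, MAF) (Hardy-Weinberg); transcripts and
    phenotype latents are linear in their parents plus Gaussian noise
    (Student-t with 3 df when ``heavy_tails``); latents are mapped to the
    clinical scales: TJ/SJ = round(28 * expit(latent)), Pain =
    100 * expit(latent), CRP = exp(latent).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(rng)
    cols: dict[str, np.ndarray] = {}
    for s in gt.snps:
        cols[s] = rng.binomial(2, gt.mafs[s], size=n_subjects).astype(float)

    def noise(sd: float) -> np.ndarray:
        if gt.heavy_tails:
            return sd * rng.standard_t(3, size=n_subjects) / math.sqrt(3.0)
        return rng.normal(0.0, sd, size=n_subjects)

    for node in gt._order:
        if node in cols:
            continue
        total = noise(gt.noise_sd[node])
        for p, b in gt.parents.get(node, []):
            total = total + b * cols[p]
        cols[node] = total

    data = {}
    for s in gt.snps:
        data[s] = cols[s]
    for g in gt.transcripts:
        data[g] = cols[g]
    data["TJ"] = np.rint(28.0 * expit(cols["TJ"])).astype(float)
    data["SJ"] = np.rint(28.0 * expit(cols["SJ"])).astype(float)
    data["Pain"] = 100.0 * expit(cols["Pain"])
    data["CRP"] = np.exp(cols["CRP"])

    subjects = [f"s{i:04d}" for i in range(n_subjects)]
    variables = (
        [Variable(s, "snp", "discrete") for s in gt.snps]
        + [Variable(g, "transcript", "continuous") for g in gt.transcripts]
        + [Variable(p, "phenotype", "continuous") for p in gt.phenotypes]
    )
    df = pd.DataFrame(data, index=subjects)
    return Cohort(subjects, variables, df)


def analytic_intervention_effect(
    gt: GroundTruth,
    transcript: str,
    fold: float,
    blocked: frozenset[str] | set[str] = frozenset(),
) -> dict[str, float]:
    """Expected latent-scale phenotype shift of a fold-change knockdown.

    Sum over directed paths transcript -> phenotype of the product of edge
    coefficients, times -ln(fold); paths through ``blocked`` nodes (e.g.
    transcripts clamped to observed values during simulation) contribute
    nothing.  Zero for non-ancestors.
    """
    if transcript not in gt.transcripts:
        raise ValueError(f"{transcript!r} is not a transcript of this ground truth")
    shift = -math.log(fold)
    children: dict[str, list[tuple[str, float]]] = {}
    for c, ps in gt.parents.items():
        for p, b in ps:
            children.setdefault(p, []).append((c, b))

    # effect[x] = sum over open paths x -> ph of the coefficient product
    out: dict[str, float] = {}
    for ph in gt.phenotypes:
        memo: dict[str, float] = {ph: 1.0}

        def eff(x: str) -> float:
            if x in memo:
                return memo[x]
            total = 0.0
            for c, b in children.get(x, []):
                if c in blocked:
                    continue
                total += b * eff(c)
            memo[x] = total
            return total

        out[ph] = shift * eff(transcript)
    return out


def model_from_ground_truth(gt: GroundTruth) -> NetworkModel:
    """Exact NetworkModel over the latent scale (for simulation oracles).

    SNP parents are folded into per-state intercepts (dosage x coefficient)
    so the fragment's switching form reproduces the generator's linear
    dosage effect exactly.
    """
    assignment: dict[str, Fragment] = {}
    for child in [*gt.transcripts, *gt.phenotypes]:
        ps = gt.parents.get(child, [])
        disc = tuple(sorted(p for p, _ in ps if p in gt.mafs))
        cont = tuple(sorted(p for p, _ in ps if p not in gt.mafs))
        coef = dict(ps)
        states = [()]
        for _ in disc:
            states = [s + (g,) for s in states for g in (0, 1, 2)]
        table = {
            s: StateParams(
                theta0=float(sum(coef[d] * g for d, g in zip(disc, s))),
                coefs=tuple(float(coef[c]) for c in cont),
                sigma=gt.noise_sd[child],
            )
            for s in states
        }
        n_states = len(states)
        assignment[child] = Fragment(
            child=child,
            parents=tuple(sorted(p for p, _ in ps)),
            discrete_parents=disc,
            continuous_parents=cont,
            param_table=table,
            kappa=n_states * (2 + len(cont)),
            score=0.0,
            n=0,
        )
    return NetworkModel(assignment)


def write_cohort_files(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the three modeling tables (genotype/expression/phenotype TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role, fname in (("snp", "genotypes.tsv"), ("transcript", "expression.tsv"),
                        ("phenotype", "phenotypes.tsv")):
        cols = cohort.names(role)
        df = cohort.data[cols].copy()
        df.insert(0, "subject", cohort.subjects)
        path = outdir / fname
        df.to_csv(path, sep="\t", index=False)
        paths[role] = path
    return paths
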