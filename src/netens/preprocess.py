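"""Genotype QC, SNP ranking, phenotype transforms and transcript filtering.

Produces the modeling-ready cohort: SNPs pass Hardy-Weinberg / MAF /
call-rate filters and are ranked by an Armitage-style trend statistic
against each phenotype; bounded clinical counts are logit-transformed
with a continuity correction and CRP is log-transformed so that every
modeled variable is continuous (or 0/1/2 discrete) on an approximately
Gaussian scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from netens.cohort_io import Cohort, Variable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms


@dataclass(frozen=True)
class TransformSpec:
    """Forward/inverse transform taking a clinical variable to modeling scale.

    ``logit_count``: y = logit((c + 0.5) / (m + 1)) keeps the endpoints 0 and
    m finite and is symmetric about m/2.  ``log``: y = ln(x).  The inverse
    returns the clinical scale; integer rounding of counts is applied only at
    reporting time (see :mod:`netens.trial`).
    """

    kind: str  # logit_count | log | identity
    m: int | None = None  # max count (28 for TJ/SJ, 100 for Pain VAS)

    def __post_init__(self) -> None:
        if self.kind not in ("logit_count", "log", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "logit_count" and (self.m is None or self.m < 1):
            raise ValueError("logit_count transform requires a max count m >= 1")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "log":
            if np.any(x <= 0):
                raise ValueError("log transform requires strictly positive values")
            return np.log(x)
        if np.any((x < 0) | (x > self.m)):
            raise ValueError(f"count outside [0, {self.m}]")
        return logit((x + 0.5) / (self.m + 1))

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        if self.kind == "log":
            return np.exp(y)
        return expit(y) * (self.m + 1) - 0.5


#: the published clinical transforms: logit counts for TJ/SJ (28 joints),
#: logit for the 0-100 Pain VAS, natural log for CRP
DEFAULT_PHENOTYPE_TRANSFORMS: dict[str, TransformSpec] = {
    "TJ": TransformSpec("logit_count", m=28),
    "SJ": TransformSpec("logit_count", m=28),
    "Pain": TransformSpec("logit_count", m=100),
    "CRP": TransformSpec("log"),
}


def transform_phenotypes(cohort: Cohort, specs: Mapping[str, TransformSpec] | None = None) -> Cohort:
    """Return a cohort with phenotype columns mapped to the modeling scale."""
    specs = DEFAULT_PHENOTYPE_TRANSFORMS if specs is None else dict(specs)
    data = cohort.data.copy()
    variables = []
    for v in cohort.variables:
        if v.role == "phenotype" and v.name in specs:
            spec = specs[v.name]
            try:
                data[v.name] = spec.forward(data[v.name].to_numpy())
            except ValueError as err:
                col = data[v.name]
                raise ValueError(f"transform of phenotype {v.name!r} failed: {err}") from err
            variables.append(
                Variable(v.name, v.role, v.domain, transform=spec.kind, transform_m=spec.m)
            )
        else:
            variables.append(v)
    return Cohort(list(cohort.subjects), variables, data)


def inverse_transform(values, spec: TransformSpec):
    """Map modeling-scale values back to the clinical scale."""
    return spec.inverse(values)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df Pearson goodness-of-fit test of genotype counts against HWE.

    Expected counts use the sample allele frequency.  A monomorphic SNP is
    in trivial equilibrium: (0, 1).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# SNP QC


def qc_filter_snps(
    cohort: Cohort,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
) -> tuple[Cohort, pd.DataFrame]:
    """Remove SNPs failing call-rate, MAF, HWE or sex-chromosome filters.

    Boundary convention follows the protocol's strict inequalities: a SNP
    is removed when call_rate < call_rate_min (exactly 0.95 is retained),
    maf < maf_min, or hwe_p < hwe_alpha.  Returns the filtered cohort and a
    per-SNP QC report.
    """
    snps = cohort.names("snp")
    if not snps:
        raise ValueError("cohort contains no SNPs")
    chrom = getattr(cohort, "snp_chromosomes", {})
    rows = []
    kept_names = []
    for snp in snps:
        col = cohort.data[snp]
        call_rate = float(col.notna().mean())
        obs = col.dropna().to_numpy()
        counts = [int(np.sum(obs == g)) for g in (0, 1, 2)]
        if obs.size:
            p_alt = (2 * counts[2] + counts[1]) / (2 * obs.size)
            maf = float(min(p_alt, 1 - p_alt))
            hwe_chi2, hwe_p = hwe_test(counts[0], counts[1], counts[2])
        else:
            maf, hwe_chi2, hwe_p = 0.0, 0.0, 1.0
        reason = ""
        if str(chrom.get(snp, "")).upper() in ("X", "Y"):
            reason = "sex_chromosome"
        elif call_rate < call_rate_min:
            reason = "call_rate"
        elif maf < maf_min:
            reason = "maf"
        elif hwe_p < hwe_alpha:
            reason = "hwe"
        kept = reason == ""
        if kept:
            kept_names.append(snp)
        rows.append(
            dict(snp=snp, call_rate=call_rate, maf=maf, hwe_chi2=hwe_chi2,
                 hwe_p=hwe_p, kept=kept, reason=reason)
        )
    report = pd.DataFrame(rows).set_index("snp")
    if not kept_names:
        logger.warning("all %d SNPs removed by QC", len(snps))
    keep_vars = [v.name for v in cohort.variables if v.role != "snp" or v.name in set(kept_names)]
    return cohort.subset(keep_vars), report


# ---------------------------------------------------------------------------
# trend test and SNP ranking


def armitage_trend_stat(
    genotype_dosages,
    phenotype_values,
    n_pcs: int = 0,
    genotype_matrix: np.ndarray | None = None,
) -> tuple[float, float]:
    """Trend association statistic n*r^2 between dosage and phenotype.

    r is the Pearson correlation; under the null the statistic is chi-square
    with 1 df.  This is the continuous-phenotype generalization of the
    Armitage trend test.  With ``n_pcs`` > 0 and a full ``genotype_matrix``
    (subjects x SNPs), dosage and phenotype are first residualized on the
    top principal components of the genotype matrix (population-
    stratification correction).
    """
    g = np.asarray(genotype_dosages, dtype=float)
    y = np.asarray(phenotype_values, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("dosage and phenotype must be 1-D of equal length")
    if g.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(g).any() or np.isnan(y).any():
        raise ValueError("trend test requires complete data")
    if np.ptp(g) == 0:
        raise ValueError("no variance in genotype dosages")
    if n_pcs > 0:
        if genotype_matrix is None:
            raise ValueError("PC correction requires the genotype matrix")
        G = np.asarray(genotype_matrix, dtype=float)
        Gc = G - G.mean(axis=0)
        u, s, _ = np.linalg.svd(Gc, full_matrices=False)
        basis = u[:, :n_pcs]
        g = g - basis @ (basis.T @ g)
        y = y - basis @ (basis.T @ y)
        if np.ptp(g) == 0:
            raise ValueError("no variance in genotype dosages after PC adjustment")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    r = np.corrcoef(g, y)[0, 1]
    stat = float(g.size * r * r)
    return stat, float(stats.chi2.sf(stat, df=1))


def rank_select_snps(pvalues: pd.DataFrame, k: int) -> list[str]:
    """Select the top-k SNPs by best (smallest) p across phenotypes.

    ``pvalues`` is SNPs x phenotypes.  Ties break lexicographically on SNP
    name so selection is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(pvalues):
        raise ValueError(f"k={k} exceeds the {len(pvalues)} available SNPs")
    best = pvalues.min(axis=1)
    order = sorted(best.index, key=lambda s: (best[s], s))
    return order[:k]


def trend_scan(cohort: Cohort, n_pcs: int = 0) -> pd.DataFrame:
    """Trend-test p-values for every (QC-passing) SNP against every phenotype."""
    snps = cohort.names("snp")
    phens = cohort.names("phenotype")
    G = cohort.data[snps].to_numpy(dtype=float) if n_pcs > 0 else None
    rows = {}
    for snp in snps:
        g = cohort.data[snp].to_numpy(dtype=float)
        ps = {}
        for ph in phens:
            y = cohort.data[ph].to_numpy(dtype=float)
            try:
                _, p = armitage_trend_stat(g, y, n_pcs=n_pcs, genotype_matrix=G)
            except ValueError:
                p = 1.0
            ps[ph] = p
        rows[snp] = ps
    return pd.DataFrame.from_dict(rows, orient="index")[phens]


# ---------------------------------------------------------------------------
# transcript filtering


def informative_transcript_filter(cohort: Cohort, k: int) -> list[str]:
    """Top-k transcripts by sample variance of log-scale expression.

    A variance-rank filter standing in for informative/non-informative gene
    calls; ties break by transcript name.
    """
    transcripts = cohort.names("transcript")
    if k > len(transcripts):
        raise ValueError(f"k={k} exceeds the {len(transcripts)} transcripts")
    var = cohort.data[transcripts].var(ddof=1)
    order = sorted(transcripts, key=lambda t: (-var[t], t))
    return order[:k]


def prepare_cohort(
    cohort: Cohort,
    top_snps: int | None = None,
    top_transcripts: int | None = None,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    n_pcs: int = 0,
    transforms: Mapping[str, TransformSpec] | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Full preprocessing: QC, transform, rank-select SNPs/transcripts.

    Returns the modeling-ready (complete-case) cohort and the SNP QC report.
    """
    qc_cohort, report = qc_filter_snps(cohort, call_rate_min, maf_min, hwe_alpha)
    transformed = transform_phenotypes(qc_cohort, transforms)
    complete = transformed.drop_incomplete()
    keep = set(complete.names())
    if top_snps is not None and complete.names("snp"):
        pv = trend_scan(complete, n_pcs=n_pcs)
        chosen = rank_select_snps(pv, min(top_snps, len(pv)))
        keep -= set(complete.names("snp")) - set(chosen)
    if top_transcripts is not None:
        chosen_t = informative_transcript_filter(
            complete, min(top_transcripts, len(complete.names("transcript")))
        )
        keep -= set(complete.names("transcript")) - set(chosen_t)
    return complete.subset([n for n in complete.names() if n in keep]), report
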