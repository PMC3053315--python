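"""Forward simulation of network models with clamping and knockdowns.

A sweep visits variables in topological order and draws each unclamped
variable from its fragment's conditional Gaussian, matching the row of
the parameter table selected by the joint discrete-parent state; clamped
variables keep their evidence values.  A knockdown of a transcript is
graph surgery: the fragment feeding the transcript is removed (it becomes
a root) and the transcript is clamped at the subject's observed value
shifted by -ln(fold) — transcripts are modeled on the natural-log scale,
so an f-fold knockdown is a -ln f shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netens.cohort_io import PHENOTYPES, Cohort
from netens.sampler import Ensemble, NetworkModel


@dataclass(frozen=True)
class Intervention:
    """A fold-change knockdown of one transcript."""

    target: str
    fold: float = 10.0

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise ValueError("fold must be positive")

    @property
    def log_shift(self) -> float:
        return -math.log(self.fold)


def forward_sample(
    model: NetworkModel, evidence: dict[str, float], rng: np.random.Generator
) -> dict[str, float]:
    """One full sweep: every variable acquires a value.

    Clamped variables copy their evidence; each other variable is drawn
    from Normal(theta0 + sum(theta_j * parent_j), sigma) of its fragment's
    state-matched parameter row.  Roots without fragments (SNPs) must be
    clamped.
    """
    values: dict[str, float] = {}
    for node in model.topo_order:
        if node in evidence:
            values[node] = float(evidence[node])
            continue
        frag = model.assignment.get(node)
        if frag is None:
            raise ValueError(f"root {node!r} has no fragment and no evidence")
        state = tuple(int(round(values[p])) for p in frag.discrete_parents)
        p = frag.params_for(state)
        mu = p.theta0
        if p.coefs:
            mu += float(
                np.dot(p.coefs, [values[q] for q in frag.continuous_parents])
            )
        values[node] = float(rng.normal(mu, p.sigma))
    return values


def apply_intervention(
    model: NetworkModel,
    evidence: dict[str, float],
    intervention: Intervention,
    roles: dict[str, str] | None = None,
) -> tuple[NetworkModel, dict[str, float]]:
    """Graph surgery for a knockdown: remove the target's fragment and clamp.

    The clamped value is the subject's observed (log-scale) expression plus
    -ln(fold).  Only transcripts may be knocked down.
    """
    target = intervention.target
    if roles is not None and roles.get(target) != "transcript":
        raise ValueError(f"knockdown target {target!r} is not a transcript")
    if target not in model.assignment and target not in evidence:
        raise ValueError(f"target {target!r} is not a variable of this model")
    if target not in evidence:
        raise ValueError(f"no observed value for target {target!r}")
    new_assignment = {c: f for c, f in model.assignment.items() if c != target}
    new_model = NetworkModel(new_assignment)
    new_evidence = dict(evidence)
    new_evidence[target] = evidence[target] + intervention.log_shift
    return new_model, new_evidence


def subject_evidence(
    cohort: Cohort, subject: str, clamp_transcripts: bool = True
) -> dict[str, float]:
    """The subject's genotype (and optionally transcript) values for clamping."""
    row = cohort.data.loc[subject]
    ev: dict[str, float] = {}
    for v in cohort.variables:
        if v.role == "snp" or (clamp_transcripts and v.role == "transcript"):
            val = row[v.name]
            if pd.isna(val):
                raise ValueError(f"missing evidence for {v.name!r} of subject {subject!r}")
            ev[v.name] = float(val)
    return ev


def simulate_subject(
    ensemble: Ensemble,
    cohort: Cohort,
    subject: str,
    intervention: Intervention | None,
    n_replicates: int,
    rng: np.random.Generator,
    propagate_transcripts: bool = False,
    phenotypes=PHENOTYPES,
) -> pd.DataFrame:
    """Replicate phenotype draws for one subject under one (or no) knockdown.

    Each replicate draws one member uniformly at random from the ensemble,
    applies the intervention, clamps the subject's genotypes and — unless
    ``propagate_transcripts`` — all transcript values except the target,
    then forward-samples the phenotypes.  Returns n_replicates rows of the
    transformed-scale phenotype values.
    """
    roles = {v.name: v.role for v in cohort.variables}
    ev = subject_evidence(cohort, subject, clamp_transcripts=not propagate_transcripts)
    if intervention is not None and propagate_transcripts:
        # target must still carry its observed value for the clamp shift
        ev.setdefault(intervention.target, float(cohort.data.loc[subject, intervention.target]))
    rows = np.empty((n_replicates, len(phenotypes)))
    k = len(ensemble)
    for r in range(n_replicates):
        model = ensemble.model(int(rng.integers(k)))
        if intervention is None:
            m, e = model, ev
        else:
            base_ev = ev if propagate_transcripts else dict(ev)
            m, e = apply_intervention(model, base_ev, intervention, roles)
        draw = forward_sample(m, e, rng)
        rows[r] = [draw[p] for p in phenotypes]
    return pd.DataFrame(rows, columns=list(phenotypes))


def summarize_medians(replicates: pd.DataFrame) -> pd.Series:
    """Per-phenotype median over replicate draws (robust point prediction)."""
    if replicates.empty:
        raise ValueError("no replicates to summarize")
    return replicates.median(axis=0)
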