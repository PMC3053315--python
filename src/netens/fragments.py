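"""Network fragments: local conditional-Gaussian models with BIC scores.

A fragment is one child variable, at most ``max_parents`` parents, and a
fitted conditional distribution.  Continuous parents enter a linear
predictor; discrete parents (SNP dosages) contribute no linear term —
their joint state switches the whole parameter set (intercept, slopes and
residual SD per state).  The score is the BIC energy

    S = S_MLE + (kappa / 2) ln N,

where S_MLE is the negative maximized Gaussian log-likelihood; lower
scores are more likely.  Networks are assembled from one fragment per
child, and the total network score is the sum of fragment scores.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from netens.cohort_io import Cohort, RunConfig

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)


class FragmentFitError(ValueError):
    """Raised when a candidate fragment cannot be fitted on the data."""


@dataclass(frozen=True)
class StateParams:
    """Parameters of the child's conditional Gaussian in one discrete state."""

    theta0: float
    coefs: tuple[float, ...]  # one per continuous parent, in parent order
    sigma: float


@dataclass(frozen=True)
class Fragment:
    """A fitted network fragment: child, parents, per-state parameters, score."""

    child: str
    parents: tuple[str, ...]
    discrete_parents: tuple[str, ...]
    continuous_parents: tuple[str, ...]
    param_table: dict[tuple[int, ...], StateParams] = field(hash=False)
    kappa: int
    score: float
    n: int

    @property
    def is_root(self) -> bool:
        return not self.parents

    def mean(self, state: tuple[int, ...], cont_values) -> float:
        p = self.param_table[state]
        return p.theta0 + float(np.dot(p.coefs, cont_values)) if p.coefs else p.theta0

    def params_for(self, state: tuple[int, ...]) -> StateParams:
        try:
            return self.param_table[state]
        except KeyError:
            raise KeyError(
                f"unseen state {state} for fragment {self.child} <- {self.parents}"
            ) from None


def fragment_to_dict(f: Fragment) -> dict:
    return {
        "child": f.child,
        "parents": list(f.parents),
        "discrete_parents": list(f.discrete_parents),
        "continuous_parents": list(f.continuous_parents),
        "param_table": [
            {"state": list(s), "theta0": p.theta0, "coefs": list(p.coefs), "sigma": p.sigma}
            for s, p in sorted(f.param_table.items())
        ],
        "kappa": f.kappa,
        "score": f.score,
        "n": f.n,
    }


def fragment_from_dict(d: dict) -> Fragment:
    table = {
        tuple(int(v) for v in row["state"]): StateParams(
            row["theta0"], tuple(row["coefs"]), row["sigma"]
        )
        for row in d["param_table"]
    }
    return Fragment(
        child=d["child"],
        parents=tuple(d["parents"]),
        discrete_parents=tuple(d["discrete_parents"]),
        continuous_parents=tuple(d["continuous_parents"]),
        param_table=table,
        kappa=int(d["kappa"]),
        score=float(d["score"]),
        n=int(d["n"]),
    )


# ---------------------------------------------------------------------------
# fitting


def _split_parents(cohort: Cohort, parents) -> tuple[tuple[str, ...], tuple[str, ...]]:
    disc, cont = [], []
    for p in sorted(parents):
        if cohort.variable(p).domain == "discrete":
            disc.append(p)
        else:
            cont.append(p)
    return tuple(disc), tuple(cont)


def _fit_arrays(
    y: np.ndarray,
    disc: np.ndarray | None,
    cont: np.ndarray | None,
    sigma_floor: float,
) -> tuple[dict[tuple[int, ...], StateParams], float, int]:
    """Group rows by joint discrete state and OLS-fit each group.

    Returns (param_table, S_MLE, n_states).  Raises FragmentFitError on
    singleton states or collinear continuous parents.
    """
    n = y.size
    if disc is not None and disc.size:
        keys = [tuple(int(v) for v in row) for row in disc]
        groups: dict[tuple[int, ...], list[int]] = {}
        for i, k in enumerate(keys):
            groups.setdefault(k, []).append(i)
    else:
        groups = {(): list(range(n))}

    table: dict[tuple[int, ...], StateParams] = {}
    nll = 0.0
    for state, idx in groups.items():
        if len(idx) < 2:
            raise FragmentFitError(f"insufficient state support: state {state} has {len(idx)} rows")
        ys = y[idx]
        if cont is not None and cont.shape[1]:
            X = np.column_stack([np.ones(len(idx)), cont[idx]])
            beta, _, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
            if rank < X.shape[1]:
                raise FragmentFitError("collinear continuous parents")
            resid = ys - X @ beta
            theta0, coefs = float(beta[0]), tuple(float(b) for b in beta[1:])
        else:
            theta0, coefs = float(ys.mean()), ()
            resid = ys - theta0
        rss = float(resid @ resid)
        sigma = max(math.sqrt(rss / len(idx)), sigma_floor)
        table[state] = StateParams(theta0, coefs, sigma)
        # NLL at the (possibly floored) sigma
        nll += 0.5 * len(idx) * (LOG_2PI + 2.0 * math.log(sigma)) + rss / (2.0 * sigma**2)
    return table, nll, len(groups)


def fit_fragment(cohort: Cohort, child: str, parents) -> Fragment:
    """Fit and BIC-score a fragment of ``child`` given ``parents``.

    Per joint discrete-parent state, ordinary least squares of the child on
    the continuous parents (intercept-only when none); the residual SD is
    the per-state MLE, floored at 1e-6 x SD(child) to keep scores finite on
    degenerate data.  kappa counts, per state, one intercept, one slope per
    continuous parent, and one sigma.
    """
    if cohort.variable(child).role == "snp":
        raise FragmentFitError(f"SNP {child!r} cannot be a fragment child")
    disc_names, cont_names = _split_parents(cohort, parents)
    cols = [child, *disc_names, *cont_names]
    sub = cohort.data[cols].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise FragmentFitError("fragment fitting requires complete data")
    y = sub[:, 0]
    nd = len(disc_names)
    disc = sub[:, 1 : 1 + nd] if nd else None
    cont = sub[:, 1 + nd :] if cont_names else None
    sd = float(y.std())
    sigma_floor = max(1e-6 * sd, 1e-12)
    table, nll, n_states = _fit_arrays(y, disc, cont, sigma_floor)
    kappa = n_states * (2 + len(cont_names))
    if cohort.N < 2:
        raise FragmentFitError("need at least 2 samples")
    score = nll + 0.5 * kappa * math.log(cohort.N)
    return Fragment(
        child=child,
        parents=tuple(sorted(parents)),
        discrete_parents=disc_names,
        continuous_parents=cont_names,
        param_table=table,
        kappa=kappa,
        score=score,
        n=cohort.N,
    )


def score_fragment(fragment: Fragment, cohort: Cohort) -> float:
    """Evaluate S = NLL + (kappa/2) ln N of a fragment's stored parameters.

    Coincides with ``fragment.score`` when the fragment was fitted on this
    cohort (MLE parameters).
    """
    if cohort.N < 2:
        raise ValueError("need at least 2 samples")
    cols = [fragment.child, *fragment.discrete_parents, *fragment.continuous_parents]
    sub = cohort.data[cols].to_numpy(dtype=float)
    y = sub[:, 0]
    nd = len(fragment.discrete_parents)
    nll = 0.0
    for i in range(y.size):
        state = tuple(int(round(v)) for v in sub[i, 1 : 1 + nd])
        p = fragment.params_for(state)
        mu = p.theta0 + float(np.dot(p.coefs, sub[i, 1 + nd :])) if p.coefs else p.theta0
        nll += 0.5 * (LOG_2PI + 2.0 * math.log(p.sigma)) + (y[i] - mu) ** 2 / (2.0 * p.sigma**2)
    return nll + 0.5 * fragment.kappa * math.log(cohort.N)


# ---------------------------------------------------------------------------
# enumeration


class FragmentLibrary:
    """Per-child lists of candidate fragments, sorted ascending by score.

    Each list is truncated to the top ``fragments_per_child`` scores but
    always contains the parentless (root) fragment, so every child can be a
    root in some network.
    """

    def __init__(self, fragments: dict[str, list[Fragment]]):
        self.fragments = {}
        for child, frags in fragments.items():
            if not frags:
                raise ValueError(f"empty fragment list for child {child!r}")
            if any(f.child != child for f in frags):
                raise ValueError("fragment filed under wrong child")
            self.fragments[child] = sorted(frags, key=lambda f: f.score)
            if not any(f.is_root for f in self.fragments[child]):
                raise ValueError(f"no root fragment for child {child!r}")

    def __getitem__(self, child: str) -> list[Fragment]:
        return self.fragments[child]

    def __contains__(self, child: str) -> bool:
        return child in self.fragments

    @property
    def children(self) -> list[str]:
        return sorted(self.fragments)

    def root_index(self, child: str) -> int:
        for i, f in enumerate(self.fragments[child]):
            if f.is_root:
                return i
        raise ValueError(f"no root fragment for child {child!r}")


def eligible_parents(
    cohort: Cohort, child: str, allow_phenotype_parents_of_transcripts: bool = False
) -> list[str]:
    """Candidate parents of ``child`` under the causal-ordering constraints.

    SNPs are always sources (never children) and may parent anything.
    Transcripts and phenotypes may affect each other in both directions,
    except that phenotypes do not parent transcripts unless explicitly
    allowed.
    """
    role = cohort.variable(child).role
    if role == "snp":
        return []
    out = []
    for v in cohort.variables:
        if v.name == child:
            continue
        if v.role == "snp":
            out.append(v.name)
        elif v.role == "transcript":
            out.append(v.name)
        elif v.role == "phenotype":
            if role == "phenotype" or allow_phenotype_parents_of_transcripts:
                out.append(v.name)
    return out


class _SufficientStats:
    """Cross-product matrices for O(1) OLS scoring of candidate fragments.

    With Z = [1, X] (all variables plus an intercept column), any
    continuous-parent OLS reduces to a small solve against sub-blocks of
    Z'Z; discrete (SNP) parents switch parameters per state, so per-state
    cross-products are precomputed per SNP.  Scores computed here are the
    same MLE BIC values :func:`fit_fragment` produces.
    """

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.names = cohort.names()
        self.col = {n: i + 1 for i, n in enumerate(self.names)}  # 0 = intercept
        X = cohort.data[self.names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise FragmentFitError("fragment enumeration requires complete data")
        self.N = X.shape[0]
        self.Z = np.column_stack([np.ones(self.N), X])
        self.G = self.Z.T @ self.Z
        self.snps = [n for n in self.names if cohort.variable(n).domain == "discrete"]
        self.snp_codes = {s: X[:, self.col[s] - 1].astype(np.int64) for s in self.snps}
        self.state_G: dict[str, dict[int, np.ndarray]] = {}
        self.state_n: dict[str, dict[int, int]] = {}
        for s in self.snps:
            code = self.snp_codes[s]
            self.state_G[s] = {}
            self.state_n[s] = {}
            for g in np.unique(code):
                rows = self.Z[code == g]
                self.state_G[s][int(g)] = rows.T @ rows
                self.state_n[s][int(g)] = rows.shape[0]
        self.sd = {n: float(X[:, self.col[n] - 1].std()) for n in self.names}

    @staticmethod
    def _state_nll(n: int, rss: float, floor: float) -> float:
        rss = max(rss, 0.0)
        sigma = max(math.sqrt(rss / n), floor)
        return 0.5 * n * (LOG_2PI + 2.0 * math.log(sigma)) + rss / (2.0 * sigma**2)

    def _ols_rss(self, G: np.ndarray, y: int, design: list[int]) -> float:
        A = G[np.ix_(design, design)]
        b = G[design, y]
        try:
            np.linalg.cholesky(A)  # PD check: fails on collinear parents
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise FragmentFitError("collinear continuous parents") from None
        return float(G[y, y] - b @ beta)

    def score(self, child: str, parents: tuple[str, ...]) -> float:
        """BIC score of the candidate; FragmentFitError on unsupported states."""
        y = self.col[child]
        disc = [p for p in parents if p in self.state_G]
        cont = [p for p in parents if p not in self.state_G]
        floor = max(1e-6 * self.sd[child], 1e-12)
        design = [0, *(self.col[c] for c in cont)]
        if not disc:
            nll = self._state_nll(self.N, self._ols_rss(self.G, y, design), floor)
            n_states = 1
        elif len(disc) == 1:
            d = disc[0]
            nll, n_states = 0.0, 0
            for g, Gd in self.state_G[d].items():
                n = self.state_n[d][g]
                if n < 2:
                    raise FragmentFitError("insufficient state support")
                nll += self._state_nll(n, self._ols_rss(Gd, y, design), floor)
                n_states += 1
        else:
            # two discrete parents: intercept-only per joint state
            code = 3 * self.snp_codes[disc[0]] + self.snp_codes[disc[1]]
            yv = self.Z[:, y]
            counts = np.bincount(code, minlength=9)
            sums = np.bincount(code, weights=yv, minlength=9)
            sq = np.bincount(code, weights=yv * yv, minlength=9)
            nll, n_states = 0.0, 0
            for s in range(9):
                n = int(counts[s])
                if n == 0:
                    continue
                if n < 2:
                    raise FragmentFitError("insufficient state support")
                rss = sq[s] - sums[s] ** 2 / n
                nll += self._state_nll(n, rss, floor)
                n_states += 1
        kappa = n_states * (2 + len(cont))
        return nll + 0.5 * kappa * math.log(self.N)


def enumerate_fragments(
    cohort: Cohort,
    config: RunConfig,
    allow_phenotype_parents_of_transcripts: bool = False,
) -> FragmentLibrary:
    """Fit and score all parent sets of size 0..max_parents for every child.

    Candidates are scored from precomputed sufficient statistics, then the
    retained top ``fragments_per_child`` per child are refitted for their
    full parameter tables; the root fragment is kept unconditionally.
    Unfittable candidates (unsupported discrete states, collinearity) are
    logged and skipped.
    """
    if config.max_parents > 2:
        raise NotImplementedError("fragment enumeration supports at most 2 parents")
    cohort = cohort.drop_incomplete()
    stats = _SufficientStats(cohort)
    out: dict[str, list[Fragment]] = {}
    n_skipped = 0
    for child in cohort.names():
        if cohort.variable(child).role == "snp":
            continue
        pool = eligible_parents(cohort, child, allow_phenotype_parents_of_transcripts)
        scored: list[tuple[float, tuple[str, ...]]] = []
        for size in range(0, config.max_parents + 1):
            for parents in itertools.combinations(pool, size):
                try:
                    scored.append((stats.score(child, parents), parents))
                except FragmentFitError:
                    n_skipped += 1
        scored.sort(key=lambda t: (t[0], t[1]))
        kept_sets = [ps for _, ps in scored[: config.fragments_per_child]]
        if () not in kept_sets:
            kept_sets.append(())
        frags = [fit_fragment(cohort, child, ps) for ps in kept_sets]
        out[child] = frags
    if n_skipped:
        logger.info("skipped %d unfittable candidate fragments", n_skipped)
    return FragmentLibrary(out)
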