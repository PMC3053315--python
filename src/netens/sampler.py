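"""Metropolis sampling of fragment-assembled DAGs with simulated annealing.

A network state assigns one library fragment to every non-SNP child; the
implied directed graph must stay acyclic and the total score is the sum of
assigned fragment scores.  The Metropolis kernel replaces one child's
fragment with another from its library (a symmetric proposal covering
add-edge, delete-edge and swap moves) and accepts with probability
min(1, exp(-(S'-S)/T)).  Annealing cools from an adaptively probed T0
toward T = 1 in stages sized so that successive score distributions keep a
target overlap (default 80%); sampling at T = 1 draws from the Boltzmann
posterior exp(-S)/Z, and the chain stops there rather than cooling
further, which would overfit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import stats

from netens.cohort_io import RunConfig
from netens.fragments import Fragment, FragmentLibrary

logger = logging.getLogger(__name__)


@dataclass
class NetworkModel:
    """One acyclic assignment of a fragment to every non-SNP child."""

    assignment: dict[str, Fragment]

    def __post_init__(self) -> None:
        for child, frag in self.assignment.items():
            if frag.child != child:
                raise ValueError(f"fragment for {child!r} has child {frag.child!r}")
        if not self.is_acyclic():
            raise ValueError("network contains a directed cycle")

    @property
    def total_score(self) -> float:
        return float(sum(f.score for f in self.assignment.values()))

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, f in self.assignment.items() for p in f.parents]

    def parents_of(self, child: str) -> tuple[str, ...]:
        f = self.assignment.get(child)
        return f.parents if f is not None else ()

    def nodes(self) -> list[str]:
        seen = set(self.assignment)
        for f in self.assignment.values():
            seen.update(f.parents)
        return sorted(seen)

    def is_acyclic(self) -> bool:
        return topological_order(self.nodes(), self.edges()) is not None

    @cached_property
    def topo_order(self) -> list[str]:
        order = topological_order(self.nodes(), self.edges())
        assert order is not None
        return order

    def descendants(self, node: str) -> set[str]:
        adj: dict[str, list[str]] = {}
        for p, c in self.edges():
            adj.setdefault(p, []).append(c)
        out: set[str] = set()
        stack = list(adj.get(node, []))
        while stack:
            v = stack.pop()
            if v not in out:
                out.add(v)
                stack.extend(adj.get(v, []))
        return out


def topological_order(nodes, edges) -> list[str] | None:
    """Kahn's algorithm; None if the edge set has a cycle."""
    indeg = {v: 0 for v in nodes}
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for p, c in edges:
        indeg[c] += 1
        adj[p].append(c)
    queue = sorted(v for v, d in indeg.items() if d == 0)
    order = []
    while queue:
        v = queue.pop(0)
        order.append(v)
        for c in adj[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return order if len(order) == len(indeg) else None


@dataclass
class Ensemble:
    """K network structures sampled at T = 1, with their shared library."""

    library: dict[str, list[Fragment]]
    assignments: list[dict[str, int]]  # per member: child -> index into library[child]
    config: RunConfig
    seed: int
    schedules: list[list[dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("ensemble has no members")

    def __len__(self) -> int:
        return len(self.assignments)

    def model(self, i: int) -> NetworkModel:
        if not hasattr(self, "_model_cache"):
            self._model_cache: dict[int, NetworkModel] = {}
        if i not in self._model_cache:
            self._model_cache[i] = NetworkModel(
                {c: self.library[c][j] for c, j in self.assignments[i].items()}
            )
        return self._model_cache[i]

    @property
    def members(self) -> list[NetworkModel]:
        return [self.model(i) for i in range(len(self))]

    def total_scores(self) -> np.ndarray:
        return np.array(
            [
                sum(self.library[c][j].score for c, j in a.items())
                for a in self.assignments
            ]
        )

    def edge_frequencies(self) -> dict[tuple[str, str], float]:
        counts: dict[tuple[str, str], int] = {}
        for a in self.assignments:
            for child, j in a.items():
                for p in self.library[child][j].parents:
                    counts[(p, child)] = counts.get((p, child), 0) + 1
        k = len(self)
        return {e: c / k for e, c in counts.items()}


# ---------------------------------------------------------------------------
# chain internals


class ChainState:
    """Mutable MCMC state: per-child fragment index plus the edge graph."""

    def __init__(self, library: FragmentLibrary, indices: dict[str, int]):
        self.library = library
        self.indices = dict(indices)
        self.children = library.children
        self.out_adj: dict[str, set[str]] = {}
        self.score = 0.0
        for child, idx in self.indices.items():
            frag = library[child][idx]
            self.score += frag.score
            for p in frag.parents:
                self.out_adj.setdefault(p, set()).add(child)

    def current(self, child: str) -> Fragment:
        return self.library[child][self.indices[child]]

    def creates_cycle(self, child: str, parents) -> bool:
        """Would assigning ``parents`` to ``child`` close a directed cycle?

        True iff some proposed parent is reachable from the child; paths out
        of the child never use the child's incoming edges, so the current
        graph's reachability is exact for the candidate.
        """
        targets = set(parents)
        if not targets:
            return False
        if child in targets:
            return True
        seen = {child}
        stack = [child]
        while stack:
            v = stack.pop()
            for c in self.out_adj.get(v, ()):
                if c in targets:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def apply(self, child: str, new_idx: int) -> None:
        old = self.current(child)
        new = self.library[child][new_idx]
        for p in old.parents:
            self.out_adj[p].discard(child)
        for p in new.parents:
            self.out_adj.setdefault(p, set()).add(child)
        self.indices[child] = new_idx
        self.score += new.score - old.score


def propose_move(state: ChainState, rng: np.random.Generator):
    """Uniform child, uniform different fragment; None if no alternative.

    Returns (child, new_index, delta_score, valid) or None for a no-op.
    ``valid`` is False when the candidate would create a cycle (such
    proposals are rejected without score evaluation but still count as
    Metropolis steps).
    """
    child = state.children[rng.integers(len(state.children))]
    frags = state.library[child]
    if len(frags) < 2:
        return None
    cur = state.indices[child]
    j = int(rng.integers(len(frags) - 1))
    if j >= cur:
        j += 1
    new = frags[j]
    if state.creates_cycle(child, new.parents):
        return child, j, math.inf, False
    delta = new.score - frags[cur].score
    return child, j, delta, True


def metropolis_step(state: ChainState, T: float, rng: np.random.Generator) -> bool:
    """One Metropolis step at temperature T; returns True if accepted."""
    if T < 1:
        raise ValueError("temperature below 1 would oversharpen the posterior")
    move = propose_move(state, rng)
    if move is None:
        return False
    child, j, delta, valid = move
    if not valid:
        return False
    if delta <= 0 or rng.random() < math.exp(-delta / T):
        state.apply(child, j)
        return True
    return False


# ---------------------------------------------------------------------------
# annealing schedule


def overlap_shift(sd: float, overlap_target: float) -> float:
    """Mean separation d of two equal-variance normals with overlap coefficient
    equal to ``overlap_target``: OVL = 2*Phi(-d/(2*sd)) => d = 2*sd*Phi^-1(1 - OVL/2)."""
    if not 0 < overlap_target <= 1:
        raise ValueError("overlap_target must lie in (0, 1]")
    return float(2.0 * sd * stats.norm.ppf(1.0 - overlap_target / 2.0))


def adapt_temperature(
    score_samples,
    T: float,
    overlap_target: float = 0.8,
    dS_dT: float | None = None,
) -> float:
    """Temperature decrement whose predicted score-mean shift keeps the
    stage-to-stage score distributions at the target overlap.

    The score distribution at T is approximated as normal; the next stage's
    mean is extrapolated linearly with slope dS/dT (estimated by finite
    differences across stages; at the first stage the fluctuation-
    dissipation identity Var(S)/T^2 is used).  Falls back to geometric
    cooling (factor 0.9) when the score variance vanishes.  Never cools
    below T = 1.
    """
    s = np.asarray(score_samples, dtype=float)
    if s.size < 2:
        raise ValueError("need score samples to adapt the temperature")
    sd = float(s.std())
    if sd == 0.0 or (dS_dT is not None and dS_dT <= 0):
        logger.info("degenerate score distribution at T=%.3g; geometric cooling", T)
        dT = -0.1 * T
        return max(dT, 1.0 - T)
    if dS_dT is None:
        dS_dT = sd * sd / (T * T)
        if dS_dT <= 0:
            return max(-0.1 * T, 1.0 - T)
    d_target = overlap_shift(sd, overlap_target)
    if d_target == 0.0:
        return 0.0
    dT = -d_target / dS_dT
    # trust region: the linear extrapolation of <S>(T) is only local, so a
    # stage never cools by more than a factor of 2 (and never below T=1)
    return max(dT, -0.5 * T, 1.0 - T)


# ---------------------------------------------------------------------------
# ensemble construction


def _random_root_state(library: FragmentLibrary) -> dict[str, int]:
    return {c: library.root_index(c) for c in library.children}


def _run_stage(
    state: ChainState, T: float, n_steps: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Run ``n_steps`` Metropolis steps; return per-step scores and acceptance."""
    scores = np.empty(n_steps)
    accepted = 0
    for i in range(n_steps):
        accepted += metropolis_step(state, T, rng)
        scores[i] = state.score
    return scores, accepted / n_steps


def _probe_initial_temperature(
    state: ChainState, rng: np.random.Generator, target_accept: float = 0.9
) -> float:
    """Double T from 1 until ``target_accept`` of the *valid* (acyclic)
    proposals are accepted; cycle-rejections are a property of the move
    kernel, not of the temperature."""
    T = 1.0
    for _ in range(40):
        accepted = valid = 0
        for _ in range(100):
            move = propose_move(state, rng)
            if move is None:
                continue
            child, j, delta, ok = move
            if not ok:
                continue
            valid += 1
            if delta <= 0 or rng.random() < math.exp(-delta / T):
                state.apply(child, j)
                accepted += 1
        if valid and accepted / valid >= target_accept:
            return T
        T *= 2.0
    logger.warning("initial-temperature probe hit cap at T=%.3g", T)
    return T


def _is_stationary(scores: np.ndarray) -> bool:
    """Stationarity heuristic: the two half-window means agree within 0.3 SD."""
    half = scores.size // 2
    a, b = scores[:half], scores[half:]
    sd = scores.std()
    return sd == 0.0 or abs(a.mean() - b.mean()) < 0.3 * sd


def _anneal_chain(
    library: FragmentLibrary,
    config: RunConfig,
    quota: int,
    rng: np.random.Generator,
) -> tuple[list[dict[str, int]], list[dict]]:
    """One annealed chain: probe T0, cool to T=1, burn in, record members."""
    n_children = len(library.children)
    steps_per_stage = max(300, 30 * n_children)
    state = ChainState(library, _random_root_state(library))
    T = _probe_initial_temperature(state, rng)
    schedule: list[dict] = []
    prev_mean: float | None = None
    prev_T: float | None = None
    while True:
        scores, acc = _run_stage(state, T, steps_per_stage, rng)
        for _ in range(2):  # extend the stage until <S> looks stationary
            if _is_stationary(scores):
                break
            more, acc = _run_stage(state, T, steps_per_stage, rng)
            scores = np.concatenate([scores[-steps_per_stage:], more])
        eq = scores[scores.size // 2 :]  # equilibrated tail
        mean, var = float(eq.mean()), float(eq.var())
        schedule.append(
            dict(T=T, mean_score=mean, var_score=var, steps=int(scores.size), acceptance=acc)
        )
        if T <= 1.0:
            break
        if prev_mean is not None and prev_T is not None and prev_T > T:
            dS_dT = (prev_mean - mean) / (prev_T - T)
        else:
            dS_dT = None
        dT = adapt_temperature(eq, T, config.overlap_target, dS_dT)
        if dT >= 0.0:
            dT = max(-0.1 * T, 1.0 - T)
        prev_mean, prev_T = mean, T
        T = max(1.0, T + dT)

    if schedule and schedule[-1]["acceptance"] < 0.001:
        logger.warning("acceptance rate %.2g%% at T=1; chain may not have converged",
                       100 * schedule[-1]["acceptance"])

    # burn-in at T=1: 10 accepted moves per child (bounded), then thinned records
    target_accepts = 10 * n_children
    accepts = 0
    for _ in range(500 * n_children):
        accepts += metropolis_step(state, 1.0, rng)
        if accepts >= target_accepts:
            break
    members: list[dict[str, int]] = []
    thin = n_children
    while len(members) < quota:
        for _ in range(thin):
            metropolis_step(state, 1.0, rng)
        members.append(dict(state.indices))
    return members, schedule


def sample_ensemble(
    library: FragmentLibrary, config: RunConfig, seed: int | None = None
) -> Ensemble:
    """Sample ``config.ensemble_size`` network structures at T = 1.

    ``config.n_chains`` independent annealed chains are run from root-only
    initial models with seeds spawned deterministically from ``seed``
    (default ``config.seed``); members are collected per chain and
    concatenated.  Output is bit-identical for a fixed (seed, n_chains).
    """
    if seed is None:
        seed = config.seed
    n_chains = min(config.n_chains, config.ensemble_size)
    base = config.ensemble_size // n_chains
    rem = config.ensemble_size % n_chains
    quotas = [base + (1 if i < rem else 0) for i in range(n_chains)]
    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    members: list[dict[str, int]] = []
    schedules: list[list[dict]] = []
    for quota, ss in zip(quotas, child_seeds):
        m, sched = _anneal_chain(library, config, quota, np.random.default_rng(ss))
        members.extend(m)
        schedules.append(sched)
    return Ensemble(
        library=dict(library.fragments),
        assignments=members,
        config=config,
        seed=seed,
        schedules=schedules,
    )


# ---------------------------------------------------------------------------
# convergence across replicate runs


def convergence_check(ensembles, tolerance: float = 0.1) -> dict:
    """Compare replicate ensembles built from the same library and config.

    Reports the maximum per-edge frequency difference across replicates,
    the spread of total-score means, and a pass/fail flag (max frequency
    difference below ``tolerance``).
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two replicate ensembles")
    ref = {k: v for k, v in ensembles[0].config.to_dict().items() if k != "seed"}
    for e in ensembles[1:]:
        other = {k: v for k, v in e.config.to_dict().items() if k != "seed"}
        if other != ref:
            raise ValueError("replicate ensembles were built with different configs")
    freqs = [e.edge_frequencies() for e in ensembles]
    all_edges = set().union(*freqs)
    max_diff = 0.0
    worst_edge = None
    for e in sorted(all_edges):
        vals = [f.get(e, 0.0) for f in freqs]
        d = max(vals) - min(vals)
        if d > max_diff:
            max_diff, worst_edge = d, e
    score_means = [float(e.total_scores().mean()) for e in ensembles]
    return dict(
        max_edge_frequency_diff=max_diff,
        worst_edge=worst_edge,
        score_means=score_means,
        score_mean_spread=max(score_means) - min(score_means),
        passed=max_diff <= tolerance,
    )
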