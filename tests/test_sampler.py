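"""Metropolis kernel, annealing schedule, and ensemble sampling."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from netens.cohort_io import RunConfig
from netens.fragments import Fragment, FragmentLibrary, StateParams
from netens.sampler import (
    ChainState,
    adapt_temperature,
    convergence_check,
    metropolis_step,
    overlap_shift,
    propose_move,
    sample_ensemble,
    topological_order,
)


def frag(child, parents, score):
    parents = tuple(sorted(parents))
    return Fragment(
        child=child,
        parents=parents,
        discrete_parents=(),
        continuous_parents=parents,
        param_table={(): StateParams(0.0, tuple(0.5 for _ in parents), 1.0)},
        kappa=2 + len(parents),
        score=score,
        n=50,
    )


def toy_library(scores: dict[str, dict[tuple, float]]) -> FragmentLibrary:
    return FragmentLibrary(
        {
            child: [frag(child, ps, s) for ps, s in table.items()]
            for child, table in scores.items()
        }
    )


def enumerate_posterior(library: FragmentLibrary):
    """Brute-force Boltzmann posterior over all acyclic joint assignments."""
    children = library.children
    weights = {}
    for combo in itertools.product(*(range(len(library[c])) for c in children)):
        frags = [library[c][i] for c, i in zip(children, combo)]
        edges = [(p, f.child) for f in frags for p in f.parents]
        nodes = set(children) | {p for e in edges for p in e}
        if topological_order(nodes, edges) is None:
            continue
        weights[combo] = math.exp(-sum(f.score for f in frags))
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


class TestProposal:
    def test_two_element_library_forced_move(self, rng):
        lib = toy_library({"y": {(): 1.0, ("x",): 2.0}})
        state = ChainState(lib, {"y": 0})
        for _ in range(20):
            child, j, _, valid = propose_move(state, rng)
            assert (child, j, valid) == ("y", 1, True)

    def test_cycle_flagged_invalid(self, rng):
        lib = toy_library({"a": {(): 1.0, ("b",): 0.5}, "b": {(): 1.0, ("a",): 0.5}})
        # lists are sorted by score: index 0 of "a" is the b -> a fragment
        state = ChainState(lib, {"a": 0, "b": 1})  # edge b -> a present, b is a root
        # the only proposal for b is a -> b, which closes a cycle
        for _ in range(50):
            child, j, delta, valid = propose_move(state, rng)
            if child == "b":
                assert not valid and delta == math.inf

    def test_uniform_over_non_current_entries(self, rng):
        lib = toy_library({"y": {(): 1.0, ("a",): 2.0, ("b",): 3.0}})
        state = ChainState(lib, {"y": 0})
        counts = {1: 0, 2: 0}
        n = 10000
        for _ in range(n):
            _, j, _, _ = propose_move(state, rng)
            counts[j] += 1
        chi2 = sum((c - n / 2) ** 2 / (n / 2) for c in counts.values())
        assert stats.chi2.sf(chi2, 1) > 0.01

    def test_single_entry_library_is_noop(self, rng):
        lib = toy_library({"y": {(): 1.0}})
        state = ChainState(lib, {"y": 0})
        assert propose_move(state, rng) is None


class TestMetropolis:
    def test_zero_delta_always_accepted(self, rng):
        lib = toy_library({"y": {(): 1.0, ("x",): 1.0}})
        state = ChainState(lib, {"y": 0})
        assert all(metropolis_step(state, 1.0, rng) for _ in range(30))

    def test_infinite_delta_never_accepted(self, rng):
        lib = toy_library({"y": {(): 1.0, ("x",): math.inf}})
        state = ChainState(lib, {"y": 0})
        assert not any(metropolis_step(state, 1.0, rng) for _ in range(30))
        assert state.indices["y"] == 0

    def test_temperature_below_one_rejected(self, rng):
        lib = toy_library({"y": {(): 1.0, ("x",): 1.0}})
        state = ChainState(lib, {"y": 0})
        with pytest.raises(ValueError):
            metropolis_step(state, 0.5, rng)

    def test_two_state_boltzmann_occupancy(self, rng):
        """Score gap ln 4 at T=1 gives long-run occupancy 4:1."""
        lib = toy_library({"y": {(): 0.0, ("x",): math.log(4.0)}})
        state = ChainState(lib, {"y": 0})
        occ = [0, 0]
        for _ in range(40000):
            metropolis_step(state, 1.0, rng)
            occ[state.indices["y"]] += 1
        frac = occ[0] / sum(occ)
        assert frac == pytest.approx(0.8, abs=0.02)


class TestAnnealSchedule:
    def test_overlap_shift_unit_normal(self):
        # overlap 0.8 between unit-variance normals <=> mean shift ~0.5067
        assert overlap_shift(1.0, 0.8) == pytest.approx(0.5067, abs=1e-3)

    def test_full_overlap_means_no_step(self, rng):
        s = rng.normal(size=200)
        assert adapt_temperature(s, 10.0, overlap_target=1.0) == 0.0

    def test_step_is_negative_and_clamped(self, rng):
        s = rng.normal(100.0, 5.0, size=200)
        dT = adapt_temperature(s, 50.0, overlap_target=0.8)
        assert dT < 0
        assert adapt_temperature(s, 1.05, overlap_target=0.8, dS_dT=1e-6) == pytest.approx(-0.05)

    def test_matches_fluctuation_dissipation_slope(self, rng):
        s = rng.normal(0.0, 20.0, size=5000)
        T = 10.0
        dT = adapt_temperature(s, T, overlap_target=0.8)
        sd = s.std()
        expected = -overlap_shift(sd, 0.8) / (sd**2 / T**2)
        assert expected > -0.5 * T  # inside the trust region
        assert dT == pytest.approx(expected, rel=1e-9)

    def test_trust_region_caps_cooling_factor(self, rng):
        # tiny variance at high T suggests a huge step; capped to T/2
        s = rng.normal(1000.0, 0.5, size=500)
        assert adapt_temperature(s, 100.0, overlap_target=0.8) == pytest.approx(-50.0)

    def test_zero_variance_falls_back_to_geometric(self):
        dT = adapt_temperature(np.full(100, 3.0), 10.0)
        assert dT == pytest.approx(-1.0)


class TestEnsemble:
    def test_member_count_and_determinism(self, small_library, small_config):
        e1 = sample_ensemble(small_library, small_config)
        e2 = sample_ensemble(small_library, small_config)
        assert len(e1) == small_config.ensemble_size
        assert e1.assignments == e2.assignments  # bit-identical under fixed seed

    def test_all_members_acyclic(self, small_ensemble):
        for m in small_ensemble.members:
            assert m.is_acyclic()

    def test_total_score_equals_resummation(self, small_ensemble):
        scores = small_ensemble.total_scores()
        for i, m in enumerate(small_ensemble.members):
            resum = sum(f.score for f in m.assignment.values())
            assert scores[i] == pytest.approx(resum, abs=1e-9)
            assert m.total_score == pytest.approx(resum, abs=1e-9)

    def test_snp_never_a_child(self, small_ensemble, small_ready):
        snps = set(small_ready.names("snp"))
        for m in small_ensemble.members:
            for _, child in m.edges():
                assert child not in snps

    def test_mean_score_non_increasing_in_temperature(self, small_ensemble):
        for sched in small_ensemble.schedules:
            means = [st["mean_score"] for st in sched]
            sds = [math.sqrt(st["var_score"]) for st in sched]
            for a, b, sd in zip(means, means[1:], sds):
                assert b <= a + 3 * max(sd, 1.0)  # cooling should not raise <S>

    def test_terminal_temperature_is_one(self, small_ensemble):
        for sched in small_ensemble.schedules:
            ts = [st["T"] for st in sched]
            assert all(x > y for x, y in zip(ts, ts[1:]))
            assert ts[-1] == 1.0

    def test_boltzmann_posterior_on_enumerable_system(self):
        """T=1 sampling frequencies match exp(-S)/Z from exhaustive
        enumeration of a 3-variable system (chi-square p > 0.01)."""
        lib = toy_library(
            {
                "a": {(): 1.0, ("b",): 0.3, ("c",): 1.2},
                "b": {(): 0.8, ("a",): 0.9},
                "c": {(): 0.5, ("a",): 0.2, ("b",): 1.1},
            }
        )
        posterior = enumerate_posterior(lib)
        rng = np.random.default_rng(999)
        state = ChainState(lib, {c: lib.root_index(c) for c in lib.children})
        for _ in range(2000):
            metropolis_step(state, 1.0, rng)
        counts: dict[tuple, int] = {}
        n = 50000
        for _ in range(n):
            metropolis_step(state, 1.0, rng)
            key = tuple(state.indices[c] for c in lib.children)
            counts[key] = counts.get(key, 0) + 1
        # chi-square against the enumerated posterior (correlated draws make
        # this conservative in the direction of larger apparent chi2; thin)
        thin_counts: dict[tuple, int] = {}
        state2 = ChainState(lib, {c: lib.root_index(c) for c in lib.children})
        rng2 = np.random.default_rng(1000)
        m = 5000
        for _ in range(m):
            for _ in range(10):
                metropolis_step(state2, 1.0, rng2)
            key = tuple(state2.indices[c] for c in lib.children)
            thin_counts[key] = thin_counts.get(key, 0) + 1
        exp = np.array([posterior[k] * m for k in posterior])
        obs = np.array([thin_counts.get(k, 0) for k in posterior])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = stats.chi2.sf(chi2, df=len(posterior) - 1)
        assert p > 0.01
        # and every sampled structure is a valid (acyclic) one
        assert set(counts) <= set(posterior)


class TestConvergenceCheck:
    def test_identical_replicates_pass(self, small_ensemble):
        report = convergence_check([small_ensemble, small_ensemble])
        assert report["max_edge_frequency_diff"] == 0.0
        assert report["passed"]

    def test_replicate_seeds_agree_on_identified_system(self):
        """Replicate runs from different seeds find the same edge-frequency
        profile when every transcript is strongly eQTL-anchored (so edge
        orientation is identified)."""
        from netens.fragments import enumerate_fragments
        from netens.preprocess import prepare_cohort
        from netens.synthdata import generate_cohort, generate_ground_truth

        gt = generate_ground_truth(
            n_snps=4, n_genes=5, n_planted=2, p_eqtl=1.0, p_cascade=0.5,
            effect_size_range=(1.0, 1.5), rng=np.random.default_rng(51),
        )
        cohort = generate_cohort(gt, 150, np.random.default_rng(52))
        ready, _ = prepare_cohort(cohort, maf_min=0.01)
        cfg = RunConfig(seed=0, ensemble_size=256, n_chains=4, fragments_per_child=8)
        lib = enumerate_fragments(ready, cfg)
        e1 = sample_ensemble(lib, cfg, seed=21)
        e2 = sample_ensemble(lib, cfg, seed=22)
        report = convergence_check([e1, e2], tolerance=0.1)
        assert report["passed"], report

    def test_mismatched_configs_fatal(self, small_library, small_config, small_ensemble):
        other_cfg = RunConfig(**{**small_config.to_dict(), "ensemble_size": 8})
        other = sample_ensemble(small_library, other_cfg)
        with pytest.raises(ValueError):
            convergence_check([small_ensemble, other])
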