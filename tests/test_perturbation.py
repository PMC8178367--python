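"""Liptak-Stouffer combination, seed-and-grow subpathway search (vs exhaustive
enumeration), permutation null, and pathway-level analysis plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pathperturb.errors import ParameterError
from pathperturb.models import GeneStat, PathwayGraph, RunConfig
from pathperturb.perturbation import (
    ScoreInput,
    analyze_pathways,
    build_score_input,
    most_perturbed_subpathway,
    permutation_p,
    stouffer_liptak,
)

from oracles import brute_force_best_subgraph


def make_score(z_map, weights=None):
    w = weights or {g: 1.0 for g in z_map}
    return ScoreInput(dict(z_map), dict(w))


def stat(gene, z, call="unchanged", log2fc=0.0):
    return GeneStat(gene, 0.0, 0.0, log2fc, 2.0 ** log2fc, 0.5, z, call)


class TestStoufferLiptak:
    def test_single_value_collapses(self):
        assert stouffer_liptak([2.5], [7.0]) == pytest.approx(2.5)

    def test_equal_unit_inputs_give_z_root_n(self):
        assert stouffer_liptak([2, 2, 2, 2]) == pytest.approx(4.0)

    def test_weighted_example(self):
        assert stouffer_liptak([1, 3], [1, 2]) == pytest.approx(7 / math.sqrt(5))
        assert stouffer_liptak([1, 3], [1, 2]) == pytest.approx(3.1305, abs=1e-4)

    def test_empty_and_bad_weights_rejected(self):
        with pytest.raises(ParameterError):
            stouffer_liptak([])
        with pytest.raises(ParameterError):
            stouffer_liptak([1.0], [0.0])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariance_of_weights(self, z, c):
        w = [1.0 + i for i in range(len(z))]
        scaled = [c * x for x in w]
        assert stouffer_liptak(z, w) == pytest.approx(stouffer_liptak(z, scaled), rel=1e-9)


class TestMostPerturbedSubpathway:
    def test_chain_example_brute_forced(self, chain_pathway, config):
        score = make_score({"a": 3.0, "b": 0.0, "c": 3.0})
        best, Z = most_perturbed_subpathway(chain_pathway, score, config)
        assert best == frozenset(["a", "b", "c"])
        assert Z == pytest.approx(6 / math.sqrt(3))
        # confirm against exhaustive enumeration of all connected subgraphs
        _, z_star = brute_force_best_subgraph([3.0, 0.0, 3.0], [(0, 1), (1, 2)])
        assert Z == pytest.approx(z_star)

    def test_all_zero_returns_lexicographically_smallest_singleton(self, chain_pathway, config):
        score = make_score({"a": 0.0, "b": 0.0, "c": 0.0})
        best, Z = most_perturbed_subpathway(chain_pathway, score, config)
        assert best == frozenset(["a"]) and Z == 0.0

    def test_single_measured_gene(self, chain_pathway, config):
        score = make_score({"b": 2.5})
        best, Z = most_perturbed_subpathway(chain_pathway, score, config)
        assert best == frozenset(["b"]) and Z == pytest.approx(2.5)

    def test_edgeless_pathway_fully_connected_convention(self, config):
        pw = PathwayGraph("p", "p", frozenset(["a", "b", "c", "d"]))
        score = make_score({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})
        best, Z = most_perturbed_subpathway(pw, score, config)
        assert best == frozenset(["a", "b", "c", "d"])
        assert Z == pytest.approx(4.0)  # whole set beats any singleton
        score2 = make_score({"a": 5.0, "b": 0.0, "c": 0.0, "d": 0.0})
        best2, Z2 = most_perturbed_subpathway(pw, score2, config)
        assert best2 == frozenset(["a"]) and Z2 == pytest.approx(5.0)

    def test_z_at_least_best_singleton_with_absolute_scoring(self, config):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        edges = tuple((genes[i], genes[i + 1], 0) for i in range(9))
        pw = PathwayGraph("p", "p", frozenset(genes), edges)
        for _ in range(20):
            score = make_score({g: float(rng.normal()) for g in genes})
            _, Z = most_perturbed_subpathway(pw, score, config)
            assert Z >= max(abs(v) for v in score.z_of.values()) - 1e-12

    def test_matches_brute_force_on_random_small_graphs(self, config):
        rng = np.random.default_rng(42)
        for trial in range(40):
            m = int(rng.integers(4, 11))
            genes = [f"g{i:02d}" for i in range(m)]
            edges = []
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.3:
                        edges.append((genes[i], genes[j], 0))
            order = rng.permutation(m)
            for pos in range(1, m):
                a, b = order[pos], order[int(rng.integers(0, pos))]
                edges.append((genes[min(a, b)], genes[max(a, b)], 0))
            pw = PathwayGraph("p", "p", frozenset(genes), tuple(edges))
            z = rng.normal(0, 2, size=m)
            score = make_score({g: float(z[i]) for i, g in enumerate(genes)})
            _, Z = most_perturbed_subpathway(pw, score, config)
            idx_edges = [(genes.index(u), genes.index(v)) for u, v, _ in pw.edges]
            _, z_star = brute_force_best_subgraph(list(np.abs(z)), idx_edges)
            assert Z >= 0.95 * z_star - 1e-12

    def test_exact_on_chains_and_stars(self, config):
        rng = np.random.default_rng(7)
        for trial in range(30):
            m = int(rng.integers(3, 12))
            genes = [f"g{i:02d}" for i in range(m)]
            if trial % 2 == 0:  # chain
                edges = tuple((genes[i], genes[i + 1], 0) for i in range(m - 1))
            else:  # star centred at g00
                edges = tuple((genes[0], genes[i], 0) for i in range(1, m))
            pw = PathwayGraph("p", "p", frozenset(genes), edges)
            z = rng.normal(0, 2, size=m)
            score = make_score({g: float(z[i]) for i, g in enumerate(genes)})
            _, Z = most_perturbed_subpathway(pw, score, config)
            idx_edges = [(genes.index(u), genes.index(v)) for u, v, _ in pw.edges]
            _, z_star = brute_force_best_subgraph(list(np.abs(z)), idx_edges)
            assert Z == pytest.approx(z_star, rel=1e-12)


class TestPermutationP:
    def _pathway_and_score(self):
        genes = [f"g{i}" for i in range(5)]
        edges = tuple((genes[i], genes[i + 1], 0) for i in range(4))
        pw = PathwayGraph("p", "p", frozenset(genes), edges)
        z_map = {f"b{i}": 0.0 for i in range(50)}
        z_map.update({g: 0.0 for g in genes})
        return pw, make_score(z_map)

    def test_observed_above_all_permutations(self):
        pw, score = self._pathway_and_score()
        cfg = RunConfig(permutations=99, rng_seed=1)
        p = permutation_p(pw, score, observed_Z=999.0, config=cfg)
        assert p == pytest.approx(1 / 100)

    def test_observed_below_all_permutations(self):
        pw, score = self._pathway_and_score()
        cfg = RunConfig(permutations=99, rng_seed=1)
        p = permutation_p(pw, score, observed_Z=-999.0, config=cfg)
        assert p == 1.0

    def test_same_seed_identical(self):
        pw, score = self._pathway_and_score()
        cfg = RunConfig(permutations=50, rng_seed=5)
        z = {**score.z_of}
        score2 = make_score(z)
        p1 = permutation_p(pw, score, 1.0, cfg, rng=np.random.default_rng(5))
        p2 = permutation_p(pw, score2, 1.0, cfg, rng=np.random.default_rng(5))
        assert p1 == p2

    def test_small_background_warns_and_samples_with_replacement(self, caplog):
        genes = [f"g{i}" for i in range(4)]
        pw = PathwayGraph("p", "p", frozenset(genes), (("g0", "g1", 0), ("g1", "g2", 0), ("g2", "g3", 0)))
        score = make_score({"g0": 1.0, "g1": 0.5})  # background of 2 < 4 measured? no: only 2 measured
        # make all 4 measured but background only those 4 minus... shrink via a bigger pathway
        score = make_score({g: 0.5 for g in genes[:3]})
        cfg = RunConfig(permutations=9, rng_seed=2)
        p = permutation_p(pw, score, 0.1, cfg)
        assert 0 < p <= 1.0


class TestAnalyzePathways:
    def test_null_pathways_have_p_one_with_zero_scores(self, config):
        stats_list = [stat(f"g{i}", 0.0) for i in range(30)]
        pathways = []
        for p in range(5):
            genes = [f"g{i}" for i in range(p * 6, p * 6 + 6)]
            edges = tuple((genes[i], genes[i + 1], 0) for i in range(5))
            pathways.append(PathwayGraph(f"pw{p}", f"pw{p}", frozenset(genes), edges))
        results = analyze_pathways(pathways, stats_list, config)
        assert len(results) == 5
        for r in results:
            assert r.p_perm == 1.0 and r.p_bonferroni == 1.0

    def test_bonferroni_multiplier_is_pathways_tested(self, chain_pathway):
        # supply 3 pathways, only 2 eligible (one has <3 measured genes)
        stats_list = [stat(g, 2.0, call="up") for g in ("a", "b", "c", "x", "y", "z")]
        small = PathwayGraph("tiny", "tiny", frozenset(["x", "q", "r"]))  # 1 measured
        other = PathwayGraph(
            "other", "other", frozenset(["x", "y", "z"]), (("x", "y", 0), ("y", "z", 0))
        )
        cfg = RunConfig(permutations=19, rng_seed=3)
        results = analyze_pathways([chain_pathway, small, other], stats_list, cfg)
        assert {r.pathway_id for r in results} == {"chain", "other"}
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_perm * 2))

    def test_bonferroni_arithmetic(self):
        assert min(1.0, 0.002 * 44) == pytest.approx(0.088)
        assert min(1.0, 0.1 * 44) == 1.0

    def test_de_and_total_counts(self, chain_pathway, config):
        stats_list = [
            stat("a", 3.0, call="up"),
            stat("b", -3.0, call="down"),
            stat("c", 0.1, call="unchanged"),
        ]
        (r,) = analyze_pathways([chain_pathway], stats_list, config)
        assert (r.de_count, r.total_count) == (2, 3)
        assert r.de_count <= r.total_count

    def test_zero_eligible_returns_empty(self, config, caplog):
        stats_list = [stat("zz", 1.0)]
        pw = PathwayGraph("p", "p", frozenset(["a", "b", "c"]))
        assert analyze_pathways([pw], stats_list, config) == []

    def test_weight_scheme_scale_invariance(self, chain_pathway):
        # multiplying all weights by a constant leaves every Z unchanged
        score = make_score({"a": 1.0, "b": 2.0, "c": 0.5}, {"a": 1.0, "b": 2.0, "c": 3.0})
        scaled = make_score({"a": 1.0, "b": 2.0, "c": 0.5}, {"a": 10.0, "b": 20.0, "c": 30.0})
        cfg = RunConfig(permutations=1)
        b1, z1 = most_perturbed_subpathway(chain_pathway, score, cfg)
        b2, z2 = most_perturbed_subpathway(chain_pathway, scaled, cfg)
        assert b1 == b2 and z1 == pytest.approx(z2, rel=1e-12)

    def test_abs_log2fc_weight_scheme(self):
        stats_list = [stat("a", 2.0, log2fc=1.5), stat("b", 1.0, log2fc=0.0)]
        cfg = RunConfig(weight_scheme="abs_log2fc", permutations=1)
        score = build_score_input(stats_list, cfg)
        assert score.weight_of["a"] == pytest.approx(1.5)
        assert score.weight_of["b"] > 0  # floored, never zero
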