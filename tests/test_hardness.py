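"""Simplified energy model, objective, and the max-cut correspondence."""

import random

import pytest

from rnadel.hardness import (
    Graph,
    MaxDelMutsInstance,
    brute_force_maxcocycle,
    brute_force_maxdelmuts,
    cocycle_value,
    extract_g_set,
    gc_script_for_subset,
    matching_partition,
    objective,
    reduce_graph,
    simple_energy,
)
from rnadel.structures import (
    EditScript,
    Mutation,
    MutationKind,
    SecondaryStructure,
)

K4 = Graph.from_edges(4, [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)])


def random_graph(rng: random.Random, n: int, p: float = 0.5) -> Graph:
    edges = [
        (u, v)
        for u in range(1, n + 1)
        for v in range(u + 1, n + 1)
        if rng.random() < p
    ]
    return Graph.from_edges(n, edges)


class TestSimpleEnergy:
    @pytest.mark.parametrize(
        "w,pairs,expected",
        [
            ("GC", [(1, 2)], -1),
            ("GA", [(1, 2)], 0),   # non-canonical pairs contribute nothing
            ("GU", [(1, 2)], -1),  # wobble counts
            ("ACGU", [], 0),
        ],
    )
    def test_pair_counting(self, w, pairs, expected):
        s = SecondaryStructure.from_pairs(len(w), pairs)
        assert simple_energy(w, s) == expected

    def test_crossing_pairs_allowed_in_theory_model(self):
        s = SecondaryStructure.from_pairs(4, [(1, 3), (2, 4)])
        assert simple_energy("GGCC", s) == -2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            simple_energy("ACG", SecondaryStructure.from_pairs(4, []))


class TestObjective:
    def test_no_competitors_reduces_to_functional_energy(self):
        inst = MaxDelMutsInstance(
            wt="GC", m=1,
            functional=SecondaryStructure.from_pairs(2, [(1, 2)]),
            competing=(),
        )
        assert objective(EditScript([]), inst) == -1

    def test_empty_script_non_canonical(self):
        inst = MaxDelMutsInstance(
            wt="AAAA", m=4,
            functional=SecondaryStructure.from_pairs(4, []),
            competing=(SecondaryStructure.from_pairs(4, [(1, 2)]),),
        )
        assert objective(EditScript([]), inst) == 0

    def test_k4_bipartition_script_scores_the_cut(self):
        inst = reduce_graph(K4)
        script = gc_script_for_subset(K4, {1, 2})
        assert objective(script, inst) == 4
        assert cocycle_value(K4, {1, 2}) == 4

    def test_indels_rejected(self):
        inst = reduce_graph(K4)
        script = EditScript([Mutation(MutationKind.DEL, 1, wt_base="A")])
        with pytest.raises(ValueError):
            objective(script, inst)

    def test_budget_enforced(self):
        inst = MaxDelMutsInstance(
            wt="AA", m=0,
            functional=SecondaryStructure.from_pairs(2, []),
            competing=(),
        )
        script = EditScript([Mutation(MutationKind.SUB, 1, wt_base="A", new_base="G")])
        with pytest.raises(ValueError):
            objective(script, inst)


class TestBruteForce:
    def test_single_pair_competitor(self):
        inst = MaxDelMutsInstance(
            wt="AA", m=1,
            functional=SecondaryStructure.from_pairs(2, []),
            competing=(SecondaryStructure.from_pairs(2, [(1, 2)]),),
        )
        script, value = brute_force_maxdelmuts(inst)
        assert value == 1  # e.g. A1U makes {U, A} canonical

    def test_dominates_random_scripts(self, rng):
        inst = reduce_graph(random_graph(rng, 5))
        _, best = brute_force_maxdelmuts(inst)
        for _ in range(20):
            script = EditScript(
                Mutation(MutationKind.SUB, p, wt_base="A",
                         new_base=rng.choice("CGU"))
                for p in range(1, 6)
            )
            assert objective(script, inst) <= best

    def test_size_guard(self):
        inst = MaxDelMutsInstance(
            wt="A" * 40, m=20,
            functional=SecondaryStructure.from_pairs(40, []),
            competing=(),
        )
        with pytest.raises(ValueError):
            brute_force_maxdelmuts(inst)

    def test_cocycle_guard(self):
        with pytest.raises(ValueError):
            brute_force_maxcocycle(Graph(21, ()))


class TestCoCycle:
    def test_empty_subset_and_complement_symmetry(self, rng):
        g = random_graph(rng, 6)
        assert cocycle_value(g, set()) == 0
        full = set(range(1, 7))
        for _ in range(10):
            subset = {v for v in full if rng.random() < 0.5}
            assert cocycle_value(g, subset) == cocycle_value(g, full - subset)

    def test_out_of_range_vertex(self):
        with pytest.raises(ValueError):
            cocycle_value(K4, {5})


class TestReduction:
    def test_construction(self):
        inst = reduce_graph(K4)
        assert inst.wt == "AAAA" and inst.m == 4
        assert inst.functional.pairs == frozenset()
        assert len(inst.competing) == 6
        assert all(len(s.pairs) == 1 for s in inst.competing)

    def test_empty_edge_set_objective_always_zero(self, rng):
        inst = reduce_graph(Graph(3, ()))
        for _ in range(5):
            script = EditScript(
                Mutation(MutationKind.SUB, p, wt_base="A",
                         new_base=rng.choice("CGU"))
                for p in range(1, 4)
            )
            assert objective(script, inst) == 0

    def test_extract_g_set(self):
        inst = reduce_graph(K4)
        all_g = EditScript(
            Mutation(MutationKind.SUB, p, wt_base="A", new_base="G")
            for p in range(1, 5)
        )
        assert extract_g_set(all_g, inst) == frozenset({1, 2, 3, 4})
        no_g = gc_script_for_subset(K4, set())
        assert extract_g_set(no_g, inst) == frozenset()

    def test_full_scripts_score_their_g_set_cut(self, rng):
        g = random_graph(rng, 6)
        inst = reduce_graph(g)
        for _ in range(20):
            script = EditScript(
                Mutation(MutationKind.SUB, p, wt_base="A",
                         new_base=rng.choice("CGU"))
                for p in range(1, 7)
            )
            assert objective(script, inst) == cocycle_value(
                g, extract_g_set(script, inst)
            )

    def test_objective_invariant_under_matching_partition(self, rng):
        g = random_graph(rng, 6)
        singleton = reduce_graph(g, partition="singleton")
        matched = reduce_graph(g, partition="matching")
        assert sum(len(s.pairs) for s in matched.competing) == len(g.edges)
        for _ in range(10):
            script = EditScript(
                Mutation(MutationKind.SUB, p, wt_base="A",
                         new_base=rng.choice("CGU"))
                for p in range(1, 7)
            )
            assert objective(script, singleton) == objective(script, matched)

    def test_graph_rejects_self_loops(self):
        with pytest.raises(ValueError):
            Graph.from_edges(3, [(2, 2)])
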