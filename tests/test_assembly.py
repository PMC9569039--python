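"""Quota splitting, randomized set assembly, coordinate projection,
validation and ranking."""

import itertools
import random

import pytest

from rnadel.assembly import (
    AssemblyConfig,
    assemble_sets,
    per_subopt_quota,
    project_to_wt_coordinates,
    validate_and_rank,
    wt_position_map,
)
from rnadel.candidates import CandidateMutation, Role
from rnadel.engines import SimpleEngine
from rnadel.fixtures import EXAMPLE_DELETIONS
from rnadel.structures import (
    EditScript,
    Mutation,
    MutationKind,
    SecondaryStructure,
    apply_edit_script,
    parse_dot_bracket,
    parse_set_name,
    structure_distance,
)

from conftest import edit_scripts, rna_sequences
from hypothesis import given, strategies as st


def cand(mut: Mutation) -> CandidateMutation:
    return CandidateMutation(mut, Role.STABILIZE_SUB, "test")


def sub_cand(pos: int, wt: str) -> CandidateMutation:
    return cand(
        Mutation(
            MutationKind.SUB, pos, wt_base=wt[pos - 1],
            new_base="A" if wt[pos - 1] != "A" else "C",
        )
    )


class TestQuota:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (100, 5, [20, 20, 20, 20, 20]),
            (7, 3, [3, 2, 2]),
            (2, 5, [1, 1, 0, 0, 0]),
            (1, 1, [1]),
        ],
    )
    def test_split(self, n, k, expected):
        quotas = per_subopt_quota(n, k)
        assert quotas == expected
        assert sum(quotas) == n

    def test_invalid(self):
        with pytest.raises(ValueError):
            per_subopt_quota(0, 3)


class TestAssembly:
    WT = "GGGGAAAACCCC"

    def _pool(self, positions):
        return [sub_cand(p, self.WT) for p in positions]

    def test_exhaustive_when_quota_large(self):
        cfg = AssemblyConfig(m=2, n_results=50, seed=0)
        scripts = assemble_sets([self._pool([2, 5, 9])], cfg)
        position_sets = {
            frozenset(m.position for m in s) for _, s in scripts
        }
        assert position_sets == {
            frozenset(c) for c in itertools.combinations([2, 5, 9], 2)
        }

    def test_quota_cuts_off_and_is_seed_reproducible(self):
        pool = self._pool([1, 2, 3, 4, 5, 6])
        cfg = AssemblyConfig(m=2, n_results=1, seed=42)
        first = assemble_sets([pool], cfg)
        assert len(first) == 1
        assert assemble_sets([pool], cfg) == first
        other = assemble_sets([pool], AssemblyConfig(m=2, n_results=1, seed=43))
        assert len(other) == 1  # possibly a different pair, but exactly one

    def test_deletion_example_single_combination(self):
        wt = EXAMPLE_DELETIONS.sequence
        pool = [
            cand(Mutation(MutationKind.DEL, 4, wt_base="U")),
            cand(Mutation(MutationKind.DEL, 6, wt_base="U")),
        ]
        scripts = assemble_sets([pool], AssemblyConfig(m=2, n_results=10, seed=0))
        assert len(scripts) == 1
        assert scripts[0][1].name == "U4-U6"
        assert (
            apply_edit_script(wt, scripts[0][1])
            == EXAMPLE_DELETIONS.mutant_sequence
        )

    def test_insufficient_positions_contribute_nothing(self):
        scripts = assemble_sets(
            [self._pool([3]), self._pool([2, 5, 9])],
            AssemblyConfig(m=2, n_results=10, seed=0),
        )
        assert all(idx == 1 for idx, _ in scripts)

    def test_candidates_sharing_a_position_never_combine(self):
        wt = self.WT
        pool = [
            cand(Mutation(MutationKind.DEL, 5, wt_base="A")),
            cand(Mutation(MutationKind.SUB, 5, wt_base="A", new_base="G")),
            cand(Mutation(MutationKind.DEL, 9, wt_base="C")),
        ]
        scripts = assemble_sets([pool], AssemblyConfig(m=2, n_results=50, seed=1))
        for _, s in scripts:
            positions = [m.position for m in s]
            assert len(set(positions)) == len(positions)


class TestProjection:
    def test_identity_for_substitution_only_scripts(self):
        s = SecondaryStructure.from_pairs(6, [(1, 6), (2, 5)])
        script = EditScript([Mutation(MutationKind.SUB, 3, wt_base="A", new_base="G")])
        assert project_to_wt_coordinates(s, script, 6) == s

    def test_deletion_shifts_back(self):
        # WT n=5, delete position 3; mutant pair (1,4) maps to WT (1,5)
        mutant = SecondaryStructure.from_pairs(4, [(1, 4)])
        script = EditScript([Mutation(MutationKind.DEL, 3, wt_base="A")])
        projected = project_to_wt_coordinates(mutant, script, 5)
        assert projected == SecondaryStructure.from_pairs(5, [(1, 5)])

    def test_insertion_pairs_dropped(self):
        # WT n=4, insert before position 2; mutant pairs touching the new
        # base disappear, others map back
        mutant = SecondaryStructure.from_pairs(5, [(2, 5)])
        script = EditScript([Mutation(MutationKind.INS, 2, new_base="G")])
        projected = project_to_wt_coordinates(mutant, script, 4)
        assert projected.pairs == frozenset()

    def test_length_bookkeeping_mismatch(self):
        mutant = SecondaryStructure.from_pairs(4, [])
        script = EditScript([Mutation(MutationKind.DEL, 1, wt_base="A")])
        with pytest.raises(ValueError):
            project_to_wt_coordinates(mutant, script, 4)

    @given(st.data())
    def test_projection_against_independent_position_map(self, data):
        wt = data.draw(rna_sequences(min_size=6, max_size=20))
        script = data.draw(edit_scripts(wt, max_size=4))
        mutant_seq = apply_edit_script(wt, script)
        # independent position map: replay edits on a list of origin labels
        labels: list[int | None] = list(range(1, len(wt) + 1))
        for m in sorted(script, key=lambda m: m.position, reverse=True):
            if m.kind is MutationKind.DEL:
                labels.pop(m.position - 1)
            elif m.kind is MutationKind.INS:
                labels.insert(m.position - 1, None)
        assert wt_position_map(script, len(wt)) == labels
        # any nested structure on the mutant projects consistently
        engine = SimpleEngine()
        mutant_structure = engine.fold_mfe(mutant_seq).structure
        projected = project_to_wt_coordinates(mutant_structure, script, len(wt))
        dropped = sum(
            1
            for i, j in mutant_structure.pairs
            if labels[i - 1] is None or labels[j - 1] is None
        )
        assert len(projected.pairs) == len(mutant_structure.pairs) - dropped


class TestValidation:
    def test_threshold_zero_keeps_everything(self):
        wt = EXAMPLE_DELETIONS.sequence
        engine = SimpleEngine()
        wt_mfe = parse_dot_bracket(EXAMPLE_DELETIONS.opt)
        scripts = [(0, parse_set_name("U4-U6", wt))]
        cfg = AssemblyConfig(m=2, n_results=10, seed=0, validation_threshold=0)
        records = validate_and_rank(scripts, wt, wt_mfe, cfg, engine)
        assert len(records) == 1
        assert records[0].distance > 0

    def test_published_deletion_set_rearranges_the_fold(self):
        """The U4-U6 mutant refolds onto the elongated suboptimal-derived
        helix and moves away from the original optimal structure."""
        wt = EXAMPLE_DELETIONS.sequence
        engine = SimpleEngine()
        script = parse_set_name("U4-U6", wt)
        mutant = apply_edit_script(wt, script)
        fold = engine.fold_mfe(mutant)
        target = parse_dot_bracket(EXAMPLE_DELETIONS.mutant_sub)
        assert len(fold.structure.pairs) >= len(target.pairs)
        projected = project_to_wt_coordinates(fold.structure, script, len(wt))
        assert (
            structure_distance(
                projected.to_dot_bracket(), EXAMPLE_DELETIONS.opt
            )
            > 0
        )

    def test_high_threshold_discards_and_ranking_is_ordered(self):
        wt = "GGGGAAAACCCCGGGGAAAACCCC"
        engine = SimpleEngine()
        wt_mfe = engine.fold_mfe(wt).structure
        pool = [sub_cand(p, wt) for p in (2, 3, 6, 7, 10, 14, 18, 22)]
        scripts = assemble_sets([pool], AssemblyConfig(m=2, n_results=20, seed=5))
        cfg = AssemblyConfig(m=2, n_results=20, seed=5, validation_threshold=2)
        records = validate_and_rank(scripts, wt, wt_mfe, cfg, engine)
        assert all(r.distance >= 2 for r in records)
        dists = [r.distance for r in records]
        assert dists == sorted(dists, reverse=True)
        assert len(records) <= 20
        assert all(len(r.script) == 2 for r in records)
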