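"""Simplified energy model, the MaxDelMuts objective, and its max-cut link.

Under the pair-counting energy model, E(w, S) is minus the number of pairs of
S whose bases form a canonical pair (AU, CG, GU).  MaxDelMuts asks, given a
wild type, a mutation budget m, a functional structure and a set of competing
structures, for the substitution script that maximizes

    E(mutant, functional) - sum_i E(mutant, competing_i)

i.e. simultaneously destabilizes the functional structure and stabilizes the
competitors.  The problem is NP-hard: any max-cut instance (MaxCoCycle —
choose a vertex subset so that a maximum number of edges have exactly one
endpoint inside) embeds into it via a poly-A wild type, budget m = n, an
empty functional structure, and one single-pair competing structure per
edge.  After mutating every position away from A, a pair contributes iff
exactly one endpoint is G, so scripts correspond to vertex subsets (the
G-positions) and objective values coincide with cut sizes.

This module makes that argument executable: brute-force solvers for both
problems, the reduction, and the explicit G/C assignment from the
equivalence argument.  Structures here are only constrained to use each
position at most once — crossing pairs are legal, unlike in the folding
pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

from .structures import (
    ALPHABET,
    EditScript,
    Mutation,
    MutationKind,
    SecondaryStructure,
    apply_edit_script,
    can_pair,
)

BRUTE_FORCE_LIMIT = 10 ** 6
COCYCLE_VERTEX_LIMIT = 20


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph on vertices 1..n_vertices."""

    n_vertices: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (1 <= u <= self.n_vertices and 1 <= v <= self.n_vertices):
                raise ValueError(f"edge {(u, v)} out of range")

    @classmethod
    def from_edges(cls, n_vertices: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        return cls(n_vertices, tuple((min(u, v), max(u, v)) for u, v in edges))


@dataclass(frozen=True)
class MaxDelMutsInstance:
    wt: str
    m: int
    functional: SecondaryStructure
    competing: tuple[SecondaryStructure, ...]

    def __post_init__(self) -> None:
        for s in (self.functional, *self.competing):
            if s.n != len(self.wt):
                raise ValueError("all structures must match the wild-type length")


def simple_energy(w: str, s: SecondaryStructure) -> int:
    """-(number of canonical pairs of s under sequence w); always <= 0."""
    if s.n != len(w):
        raise ValueError(f"length mismatch: structure n={s.n}, |w|={len(w)}")
    return -sum(1 for i, j in s.pairs if can_pair(w[i - 1], w[j - 1]))


def objective(script: EditScript, inst: MaxDelMutsInstance) -> int:
    """E(mutant, functional) - sum E(mutant, competing_i).

    The theory model is substitution-only (indels would re-index the
    structures); scripts containing indels are rejected.
    """
    if any(m.kind is not MutationKind.SUB for m in script):
        raise ValueError("the theory objective is defined for substitutions only")
    if len(script) > inst.m:
        raise ValueError(f"script has {len(script)} > budget m={inst.m} mutations")
    mutant = apply_edit_script(inst.wt, script)
    return simple_energy(mutant, inst.functional) - sum(
        simple_energy(mutant, s) for s in inst.competing
    )


def brute_force_maxdelmuts(
    inst: MaxDelMutsInstance, limit: int = BRUTE_FORCE_LIMIT
) -> tuple[EditScript, int]:
    """Exhaustive maximization over all scripts of exactly m substitutions.

    Ties broken by enumeration order: positions lexicographic, replacement
    bases alphabetical.  Guarded by C(n, m) * 3^m <= limit.
    """
    n, m = len(inst.wt), inst.m
    size = comb(n, m) * 3 ** m
    if size > limit:
        raise ValueError(
            f"instance too large for brute force: C({n},{m})*3^{m} = {size} > {limit}"
        )
    best_script: EditScript | None = None
    best_value: int | None = None
    for positions in itertools.combinations(range(1, n + 1), m):
        choices = [sorted(ALPHABET - {inst.wt[p - 1]}) for p in positions]
        for bases in itertools.product(*choices):
            script = EditScript(
                Mutation(MutationKind.SUB, p, wt_base=inst.wt[p - 1], new_base=b)
                for p, b in zip(positions, bases)
            )
            value = objective(script, inst)
            if best_value is None or value > best_value:
                best_script, best_value = script, value
    if best_script is None:  # m == 0
        best_script = EditScript(())
        best_value = objective(best_script, inst)
    return best_script, best_value


def singleton_partition(g: Graph) -> tuple[SecondaryStructure, ...]:
    """One competing structure per edge (each edge as a sole pair)."""
    return tuple(
        SecondaryStructure.from_pairs(g.n_vertices, [e]) for e in g.edges
    )


def matching_partition(g: Graph) -> tuple[SecondaryStructure, ...]:
    """Greedy partition of the edge set into matchings.

    An alternative valid partition (each position used at most once per
    structure); the objective is invariant to the choice of partition since
    it sums over all parts.
    """
    remaining = list(g.edges)
    parts: list[SecondaryStructure] = []
    while remaining:
        used: set[int] = set()
        matched: list[tuple[int, int]] = []
        rest: list[tuple[int, int]] = []
        for u, v in remaining:
            if u in used or v in used:
                rest.append((u, v))
            else:
                matched.append((u, v))
                used.update((u, v))
        parts.append(SecondaryStructure.from_pairs(g.n_vertices, matched))
        remaining = rest
    return tuple(parts)


def reduce_graph(g: Graph, partition: str = "singleton") -> MaxDelMutsInstance:
    """Embed a MaxCoCycle instance into MaxDelMuts.

    wt = A^n, m = n, empty functional structure, competing structures a
    partition of the edge set.
    """
    if partition == "singleton":
        competing = singleton_partition(g)
    elif partition == "matching":
        competing = matching_partition(g)
    else:
        raise ValueError(f"unknown partition scheme {partition!r}")
    return MaxDelMutsInstance(
        wt="A" * g.n_vertices,
        m=g.n_vertices,
        functional=SecondaryStructure(g.n_vertices, frozenset()),
        competing=competing,
    )


def cocycle_value(g: Graph, subset: set[int] | frozenset[int]) -> int:
    """Number of edges with exactly one endpoint in *subset* (the cut size)."""
    subset = set(subset)
    bad = subset - set(range(1, g.n_vertices + 1))
    if bad:
        raise ValueError(f"vertices out of range: {sorted(bad)}")
    return sum(1 for u, v in g.edges if (u in subset) != (v in subset))


def brute_force_maxcocycle(g: Graph) -> tuple[frozenset[int], int]:
    """Exhaustive max-cut over all 2^n vertex subsets (guarded at n <= 20)."""
    if g.n_vertices > COCYCLE_VERTEX_LIMIT:
        raise ValueError(
            f"brute force refused for n={g.n_vertices} > {COCYCLE_VERTEX_LIMIT}"
        )
    best_subset: frozenset[int] = frozenset()
    best_value = 0
    vertices = list(range(1, g.n_vertices + 1))
    for r in range(g.n_vertices + 1):
        for combo in itertools.combinations(vertices, r):
            value = cocycle_value(g, set(combo))
            if value > best_value:
                best_subset, best_value = frozenset(combo), value
    return best_subset, best_value


def extract_g_set(script: EditScript, inst: MaxDelMutsInstance) -> frozenset[int]:
    """Positions whose mutant base is G — the vertex subset a script encodes."""
    mutant = apply_edit_script(inst.wt, script)
    return frozenset(i for i, b in enumerate(mutant, 1) if b == "G")


def gc_script_for_subset(g: Graph, subset: set[int] | frozenset[int]) -> EditScript:
    """The explicit construction from the equivalence argument: set the
    subset's positions to G and all others to C (on the reduced wt = A^n)."""
    return EditScript(
        Mutation(
            MutationKind.SUB, v, wt_base="A",
            new_base="G" if v in subset else "C",
        )
        for v in range(1, g.n_vertices + 1)
    )
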