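"""Assembly of single-point candidates into validated M-point mutation sets.

Each suboptimal representative receives a quota of the requested N output
sets (floor(N/k) each, remainder to the most distant representatives).  Sets
are assembled per representative by a randomized recursive enumeration over
that representative's candidate pool: the branch order over (mutation type,
candidate) is reshuffled by the seeded RNG at every recursion level, giving
type-diverse output, and the enumeration stops at the quota or when all
combinations are exhausted.  Sets never mix candidates from different
suboptimal representatives.

Every assembled set is validated by refolding the mutant, projecting its
structure back onto wild-type coordinates, and requiring the projected
distance from the wild-type MFE structure to meet a threshold ("distant
enough" to count as deleterious); survivors are ranked by that distance.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

from .candidates import CandidateMutation
from .engines import FoldResult
from .structures import (
    EditScript,
    Mutation,
    MutationKind,
    SecondaryStructure,
    apply_edit_script,
    structure_distance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyConfig:
    m: int = 2
    n_results: int = 100
    allowed: frozenset[MutationKind] = frozenset(MutationKind)
    seed: int = 0
    validation_threshold: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_results < 1:
            raise ValueError("M and N must be >= 1")
        if not self.allowed:
            raise ValueError("at least one mutation type must be allowed")


@dataclass(frozen=True)
class MutationRecord:
    """An assembled, validated M-point mutant."""

    name: str
    script: EditScript
    mutant_seq: str
    mutant_structure: SecondaryStructure
    energy: float
    distance: int
    source_sub: int


def per_subopt_quota(n_results: int, k: int) -> list[int]:
    """Split N output slots over k suboptimal representatives.

    floor(N/k) each; the remainder goes one-each to the first (most distant)
    representatives.  Sums to N.
    """
    if n_results < 1 or k < 1:
        raise ValueError("N and k must be >= 1")
    base, rem = divmod(n_results, k)
    return [base + (1 if idx < rem else 0) for idx in range(k)]


def _enumerate_sets(
    pool: Sequence[CandidateMutation],
    m: int,
    quota: int,
    rng: random.Random,
) -> list[EditScript]:
    """Up to *quota* distinct m-subsets of *pool* with distinct positions.

    Standard combination recursion over a pool whose order is reshuffled
    (types first, then candidates within type) at every level, so truncation
    at the quota still yields a type-diverse random selection while distinct
    subsets are guaranteed.
    """
    out: list[EditScript] = []

    def shuffled(cands: Sequence[CandidateMutation]) -> list[CandidateMutation]:
        by_kind: dict[MutationKind, list[CandidateMutation]] = {}
        for c in cands:
            by_kind.setdefault(c.mutation.kind, []).append(c)
        kinds = list(by_kind)
        rng.shuffle(kinds)
        ordered: list[CandidateMutation] = []
        for kind in kinds:
            group = by_kind[kind]
            rng.shuffle(group)
            ordered.extend(group)
        return ordered

    def rec(cands: Sequence[CandidateMutation], chosen: list[Mutation]) -> None:
        if len(out) >= quota:
            return
        if len(chosen) == m:
            out.append(EditScript(chosen))
            return
        if len(cands) < m - len(chosen):
            return
        order = shuffled(cands)
        for idx, cand in enumerate(order):
            if len(out) >= quota:
                return
            rest = [
                c for c in order[idx + 1:]
                if c.mutation.position != cand.mutation.position
            ]
            rec(rest, chosen + [cand.mutation])

    if quota > 0:
        rec(list(pool), [])
    return out


def assemble_sets(
    candidates_by_sub: Sequence[Sequence[CandidateMutation]],
    cfg: AssemblyConfig,
) -> list[tuple[int, EditScript]]:
    """Assemble up to N scripts of exactly M mutations, tagged with the index
    of the generating suboptimal representative."""
    rng = random.Random(cfg.seed)
    quotas = per_subopt_quota(cfg.n_results, len(candidates_by_sub))
    scripts: list[tuple[int, EditScript]] = []
    for idx, (pool, quota) in enumerate(zip(candidates_by_sub, quotas)):
        distinct_positions = len({c.mutation.position for c in pool})
        if distinct_positions < cfg.m:
            logger.info(
                "suboptimal %d: only %d candidate positions < M=%d, skipped",
                idx, distinct_positions, cfg.m,
            )
            continue
        sets = _enumerate_sets(pool, cfg.m, quota, rng)
        scripts.extend((idx, s) for s in sets)
    return scripts


def wt_position_map(script: EditScript, wt_len: int) -> list[int | None]:
    """Mutant position (1-based, as list index 0..) -> originating wild-type
    position, or None for inserted bases."""
    deleted = {m.position for m in script if m.kind is MutationKind.DEL}
    inserted = {m.position for m in script if m.kind is MutationKind.INS}
    mapping: list[int | None] = []
    for pos in range(1, wt_len + 2):
        if pos in inserted:
            mapping.append(None)
        if pos <= wt_len and pos not in deleted:
            mapping.append(pos)
    return mapping


def project_to_wt_coordinates(
    mutant_structure: SecondaryStructure,
    script: EditScript,
    wt_len: int | None = None,
) -> SecondaryStructure:
    """Re-index a mutant structure onto wild-type coordinates.

    Pairs with an endpoint on an inserted base are dropped; remaining pairs
    keep their originating wild-type positions (deleted positions simply
    become unpaired in the projection).  This makes structures of
    indel-mutants comparable with the wild-type MFE structure.
    """
    n_del = script.count(MutationKind.DEL)
    n_ins = script.count(MutationKind.INS)
    if wt_len is None:
        wt_len = mutant_structure.n + n_del - n_ins
    mapping = wt_position_map(script, wt_len)
    if len(mapping) != mutant_structure.n:
        raise ValueError(
            f"length bookkeeping mismatch: mutant n={mutant_structure.n}, "
            f"map length {len(mapping)}"
        )
    projected = set()
    for i, j in mutant_structure.pairs:
        wi, wj = mapping[i - 1], mapping[j - 1]
        if wi is not None and wj is not None:
            projected.add((wi, wj))
    return SecondaryStructure(wt_len, frozenset(projected))


def validate_and_rank(
    scripts: Sequence[tuple[int, EditScript]],
    wt: str,
    wt_mfe: SecondaryStructure,
    cfg: AssemblyConfig,
    engine,
) -> list[MutationRecord]:
    """Refold each mutant, keep those far enough from the wild-type MFE
    structure, rank by distance (descending; ties by energy then name)."""
    wt_db = wt_mfe.to_dot_bracket()
    records: list[MutationRecord] = []
    seen: set[str] = set()
    for sub_idx, script in scripts:
        if script.name in seen:
            continue  # identical set assembled from another representative
        seen.add(script.name)
        mutant = apply_edit_script(wt, script)
        try:
            fold = engine.fold_mfe(mutant)
        except Exception as exc:
            raise RuntimeError(
                f"engine failed on mutant {script.name}: {exc}"
            ) from exc
        projected = project_to_wt_coordinates(fold.structure, script, len(wt))
        dist = structure_distance(projected.to_dot_bracket(), wt_db)
        if dist < cfg.validation_threshold:
            logger.info(
                "discarding %s: projected distance %d < threshold %d",
                script.name, dist, cfg.validation_threshold,
            )
            continue
        records.append(
            MutationRecord(
                name=script.name,
                script=script,
                mutant_seq=mutant,
                mutant_structure=fold.structure,
                energy=fold.energy,
                distance=dist,
                source_sub=sub_idx,
            )
        )
    records.sort(key=lambda r: (-r.distance, r.energy, r.name))
    return records[: cfg.n_results]
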