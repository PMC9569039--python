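"""Derivation of "good" single-point mutations from structure pairs.

Given the optimal structure and one distant suboptimal structure, the method
looks for mutations that push the folding landscape toward the suboptimal
fold from two directions:

* **Stabilizers** act between coaxially nested consecutive stems of the
  suboptimal structure (the bulge / interior loop separating them):

  - deleting a loop nucleotide merges (elongates) the flanking stems;
  - substituting a loop nucleotide to the Watson-Crick complement of the
    base facing it across the loop zips the two stems together;
  - for one-sided or asymmetric loops, inserting a complementary base on the
    narrow side lets an unmatched base on the wide side pair up.

* **Destabilizers** attack the stems of the optimal structure.  Breaking the
  innermost pair of a helix shortens it: the substitution replaces the 5'
  base of that pair with its partner's own base (two identical bases can
  never pair canonically), and the deletion removes it.  Insertions bulge a
  helix from within: exactly one insertion candidate is generated per
  optimal stem, in the middle of its 5' strand — one is sufficient to
  destabilize the helix, and allowing more would blow up combinatorially.

A mutation produced independently by both derivations is reported once with
role ``BOTH``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .structures import (
    CANONICAL_PAIRS,
    WC_COMPLEMENT,
    Mutation,
    MutationKind,
    SecondaryStructure,
    Stem,
    can_pair,
    find_stems,
)


class Role(enum.Enum):
    STABILIZE_SUB = "STABILIZE_SUB"
    DESTABILIZE_OPT = "DESTABILIZE_OPT"
    BOTH = "BOTH"


@dataclass(frozen=True)
class StemGap:
    """The unpaired region between two coaxially nested consecutive stems.

    ``outer`` encloses ``inner``; the 5' gap spans the positions between the
    outer stem's innermost opening base and the inner stem's outermost
    opening base, the 3' gap mirrors this on the other strand.  Either side
    may be empty (a bulge) but not both (maximality of stems).
    """

    outer: Stem
    inner: Stem
    five_prime_gap: tuple[int, ...]
    three_prime_gap: tuple[int, ...]


@dataclass(frozen=True)
class CandidateMutation:
    mutation: Mutation
    role: Role
    source: str


def find_stem_gaps(s: SecondaryStructure) -> list[StemGap]:
    """One gap per (outer, inner) stem pair where the inner stem is the
    unique stem directly nested inside the outer's innermost pair with only
    unpaired positions between them (no gap across multiloop branches)."""
    stems = find_stems(s)
    gaps: list[StemGap] = []
    for outer in stems:
        p, q = outer.inner
        children = [
            st for st in stems
            if p < st.outer[0] and st.outer[1] < q
            # directly nested: no third stem strictly between outer and st
            and not any(
                p < other.outer[0] <= st.outer[0]
                and st.outer[1] <= other.outer[1] < q
                and other is not st
                for other in stems
            )
        ]
        if len(children) != 1:
            continue
        inner = children[0]
        pp, qq = inner.outer
        gaps.append(
            StemGap(
                outer,
                inner,
                tuple(range(p + 1, pp)),
                tuple(range(qq + 1, q)),
            )
        )
    return gaps


def _first_non_pairing_base(partner_base: str, exclude: str | None = None) -> str:
    """Alphabetically first base forming no canonical pair with partner_base."""
    for b in "ACGU":
        if b != exclude and not can_pair(b, partner_base):
            return b
    raise RuntimeError("unreachable: every base has a non-pairing alternative")


def _stabilizers(
    seq: str, sub: SecondaryStructure, allowed: set[MutationKind]
) -> list[tuple[Mutation, str]]:
    out: list[tuple[Mutation, str]] = []
    for gap in find_stem_gaps(sub):
        tag = f"sub gap {gap.outer.inner}/{gap.inner.outer}"
        five, three = gap.five_prime_gap, gap.three_prime_gap
        a, b = len(five), len(three)
        p, q = gap.outer.inner
        if MutationKind.DEL in allowed:
            for x in five + three:
                out.append((Mutation(MutationKind.DEL, x, wt_base=seq[x - 1]), tag))
        if MutationKind.SUB in allowed:
            # aligned slots: t-th 5' position faces the t-th-from-last 3' one
            for t in range(1, min(a, b) + 1):
                x, y = p + t, q - t
                if can_pair(seq[x - 1], seq[y - 1]):
                    continue  # already canonical, nothing to fix
                comp_y = WC_COMPLEMENT[seq[y - 1]]
                if comp_y != seq[x - 1]:
                    out.append(
                        (Mutation(MutationKind.SUB, x, wt_base=seq[x - 1],
                                  new_base=comp_y), tag)
                    )
                comp_x = WC_COMPLEMENT[seq[x - 1]]
                if comp_x != seq[y - 1]:
                    out.append(
                        (Mutation(MutationKind.SUB, y, wt_base=seq[y - 1],
                                  new_base=comp_x), tag)
                    )
        if MutationKind.INS in allowed and a != b:
            # asymmetric loop: pair the unmatched wide-side bases by
            # inserting their complements on the narrow side, adjacent to
            # the outer stem's closing base.
            if a > b:
                unmatched = five[b:]
                coord = q - b  # insert immediately before position q-b
            else:
                unmatched = three[: b - a]
                coord = p + a + 1  # insert immediately after position p+a
            for x in unmatched:
                out.append(
                    (Mutation(MutationKind.INS, coord,
                              new_base=WC_COMPLEMENT[seq[x - 1]]), tag)
                )
    return out


def _destabilizers(
    seq: str,
    opt: SecondaryStructure,
    allowed: set[MutationKind],
    attack_size1_stems: bool,
) -> list[tuple[Mutation, str]]:
    out: list[tuple[Mutation, str]] = []
    for stem in find_stems(opt):
        if stem.size < 2 and not attack_size1_stems:
            continue
        tag = f"opt stem {stem.outer}"
        p, q = stem.inner  # innermost pair: breaking it shortens the helix
        if MutationKind.SUB in allowed:
            partner_base = seq[q - 1]
            if partner_base != seq[p - 1]:  # equal would mean a non-canonical pair
                out.append(
                    (Mutation(MutationKind.SUB, p, wt_base=seq[p - 1],
                              new_base=partner_base), tag)
                )
        if MutationKind.DEL in allowed:
            out.append((Mutation(MutationKind.DEL, p, wt_base=seq[p - 1]), tag))
        if MutationKind.INS in allowed:
            i, j = stem.outer
            mid5 = (i + p) // 2  # middle of the 5' strand run i..p
            partner_of_mid5 = j - (mid5 - i)
            base = _first_non_pairing_base(seq[partner_of_mid5 - 1])
            out.append((Mutation(MutationKind.INS, mid5, new_base=base), tag))
    return out


def collect_candidates(
    seq: str,
    opt: SecondaryStructure,
    sub: SecondaryStructure,
    allowed: set[MutationKind] | frozenset[MutationKind],
    attack_size1_stems: bool = False,
) -> list[CandidateMutation]:
    """Union of stabilizing and destabilizing single-point candidates.

    Identical mutations arising from both derivations are merged with role
    promoted to ``BOTH``.  Returned in ascending position order.
    """
    allowed = set(allowed)
    if opt.n != len(seq) or sub.n != len(seq):
        raise ValueError("structures and sequence must have the same length")
    merged: dict[Mutation, CandidateMutation] = {}
    for mut, tag in _stabilizers(seq, sub, allowed):
        if mut in merged:
            continue
        merged[mut] = CandidateMutation(mut, Role.STABILIZE_SUB, tag)
    for mut, tag in _destabilizers(seq, opt, allowed, attack_size1_stems):
        if mut in merged:
            prev = merged[mut]
            merged[mut] = CandidateMutation(
                mut, Role.BOTH, f"{prev.source}; {tag}"
            )
        else:
            merged[mut] = CandidateMutation(mut, Role.DESTABILIZE_OPT, tag)
    return sorted(
        merged.values(), key=lambda c: (c.mutation.position, c.mutation.kind.value)
    )
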