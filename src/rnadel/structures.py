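"""Sequences, secondary structures, stems, mutations and edit scripts.

Coordinates are 1-based throughout, matching the naming convention used for
mutations ("G4C" substitutes position 4).  A secondary structure is a set of
base pairs in which each position occurs at most once; structures parsed from
dot-bracket text are additionally non-crossing (properly nested), while the
theory-level structures used by :mod:`rnadel.hardness` may cross.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGU")

#: Watson-Crick complement (used when designing stabilizing mutations).
WC_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Canonical pairs, wobble included.  Only these contribute energy in the
#: simplified pair-counting model, and a "non-pairing" base choice for
#: destabilization must avoid all of them.
CANONICAL_PAIRS = frozenset(
    {frozenset("AU"), frozenset("CG"), frozenset("GU")}
)

MAX_PIPELINE_LENGTH = 1000


class SequenceError(ValueError):
    pass


class StructureError(ValueError):
    pass


def can_pair(a: str, b: str) -> bool:
    """True iff *a* and *b* form a canonical pair (AU, CG or GU)."""
    return frozenset((a, b)) in CANONICAL_PAIRS


def clean_sequence(text: str, *, max_length: int | None = None) -> str:
    """Normalize raw sequence text to an uppercase ACGU string.

    T (DNA dialect, common in FASTA files) is converted to U with a logged
    warning.  Any other character is rejected.
    """
    seq = text.strip().upper()
    if "T" in seq:
        logger.warning("sequence contains T; converting to U")
        seq = seq.replace("T", "U")
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")
    if max_length is not None and len(seq) > max_length:
        raise SequenceError(
            f"sequence of {len(seq)} nt exceeds the {max_length}-nt limit"
        )
    return seq


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over positions 1..n.

    ``pairs`` holds ``(i, j)`` tuples with ``1 <= i < j <= n``; each position
    occurs in at most one pair.  Crossing pairs are allowed at this level
    (the theory model needs them); dot-bracket rendering requires nesting.
    """

    n: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"pair {(i, j)} out of range for n={self.n}")
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair {(i, j)}")
            seen.add(i)
            seen.add(j)

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        return cls(n, frozenset((min(i, j), max(i, j)) for i, j in pairs))

    @classmethod
    def from_dot_bracket(cls, text: str) -> "SecondaryStructure":
        return parse_dot_bracket(text)

    def partner_table(self) -> dict[int, int]:
        table: dict[int, int] = {}
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def is_nested(self) -> bool:
        pairs = sorted(self.pairs)
        for a in range(len(pairs)):
            i, j = pairs[a]
            for k, l in pairs[a + 1:]:
                if k > j:
                    break
                if i < k <= j < l:
                    return False
        return True

    def to_dot_bracket(self) -> str:
        return to_dot_bracket(self)

    def __len__(self) -> int:
        return len(self.pairs)


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string by stack matching.

    Raises :class:`StructureError` identifying the offending 1-based index
    for unbalanced brackets or foreign characters.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {idx}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(len(text), frozenset(pairs))


def to_dot_bracket(s: SecondaryStructure) -> str:
    """Render a nested structure as a dot-bracket string (inverse of parsing)."""
    if not s.is_nested():
        raise StructureError("crossing pairs cannot be rendered as dot-bracket")
    chars = ["."] * s.n
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def bp_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Symmetric-difference base-pair distance |pairs(s1) XOR pairs(s2)|."""
    if s1.n != s2.n:
        raise StructureError(f"length mismatch: {s1.n} vs {s2.n}")
    return len(s1.pairs ^ s2.pairs)


def structure_distance(s1, s2) -> int:
    """Positionwise (Hamming) distance between two structures.

    The number of positions whose dot-bracket character differs, i.e. whose
    pairing status (opening, closing or unpaired) disagrees.  This is the
    distance used throughout the prediction pipeline — it reproduces the
    reference distances of the bundled 93-nt benchmark exactly, whereas the
    set-based :func:`bp_distance` does not.  Accepts dot-bracket strings or
    :class:`SecondaryStructure` objects (strings avoid a parse when streaming
    large suboptimal ensembles).
    """
    a = s1 if isinstance(s1, str) else s1.to_dot_bracket()
    b = s2 if isinstance(s2, str) else s2.to_dot_bracket()
    if len(a) != len(b):
        raise StructureError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class Stem:
    """A maximal helix: ``size`` stacked pairs (i+t, j-t) for t = 0..size-1."""

    outer: tuple[int, int]
    size: int

    @property
    def inner(self) -> tuple[int, int]:
        i, j = self.outer
        return (i + self.size - 1, j - self.size + 1)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        i, j = self.outer
        return [(i + t, j - t) for t in range(self.size)]

    def five_prime_positions(self) -> range:
        return range(self.outer[0], self.outer[0] + self.size)

    def three_prime_positions(self) -> range:
        return range(self.outer[1] - self.size + 1, self.outer[1] + 1)


def find_stems(s: SecondaryStructure) -> list[Stem]:
    """Decompose a nested structure into maximal stacks of consecutive pairs.

    Every pair belongs to exactly one stem; stems are returned 5'-to-3' by
    their outer opening position.
    """
    pairs = sorted(s.pairs)
    pair_set = s.pairs
    stems: list[Stem] = []
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not the outer pair of its stack
        size = 1
        while (i + size, j - size) in pair_set:
            size += 1
        stems.append(Stem((i, j), size))
    stems.sort(key=lambda st: st.outer[0])
    return stems


class MutationKind(enum.Enum):
    SUB = "SUB"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class Mutation:
    """A typed single-point edit in wild-type coordinates.

    For insertions the new base is placed immediately before the wild-type
    base at ``position`` (position n+1 appends).  ``wt_base`` records the
    replaced/removed residue for substitutions and deletions.
    """

    kind: MutationKind
    position: int
    wt_base: str | None = None
    new_base: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind is MutationKind.SUB:
            if self.wt_base is None or self.new_base is None:
                raise ValueError("substitution needs wt_base and new_base")
            if self.new_base == self.wt_base:
                raise ValueError("substitution must change the base")
        elif self.kind is MutationKind.DEL:
            if self.wt_base is None or self.new_base is not None:
                raise ValueError("deletion needs wt_base only")
        elif self.kind is MutationKind.INS:
            if self.new_base is None or self.wt_base is not None:
                raise ValueError("insertion needs new_base only")
        for base in (self.wt_base, self.new_base):
            if base is not None and base not in ALPHABET:
                raise ValueError(f"invalid base {base!r}")


def format_mutation_name(m: Mutation) -> str:
    """Render the naming grammar: SUB "G4C", DEL "U4", INS "15A"."""
    if m.kind is MutationKind.SUB:
        return f"{m.wt_base}{m.position}{m.new_base}"
    if m.kind is MutationKind.DEL:
        return f"{m.wt_base}{m.position}"
    return f"{m.position}{m.new_base}"


_NAME_RE = re.compile(
    r"^(?:(?P<sub>(?P<swt>[ACGU])(?P<spos>\d+)(?P<snew>[ACGU]))"
    r"|(?P<del>(?P<dwt>[ACGU])(?P<dpos>\d+))"
    r"|(?P<ins>(?P<ipos>\d+)(?P<inew>[ACGU])))$"
)


def parse_mutation_name(text: str, wt: str) -> Mutation:
    """Inverse of :func:`format_mutation_name`; verifies wt_base against *wt*."""
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation name {text!r}")
    if m.group("sub"):
        pos, wt_base, new = int(m.group("spos")), m.group("swt"), m.group("snew")
        kind = MutationKind.SUB
    elif m.group("del"):
        pos, wt_base, new = int(m.group("dpos")), m.group("dwt"), None
        kind = MutationKind.DEL
    else:
        pos, wt_base, new = int(m.group("ipos")), None, m.group("inew")
        kind = MutationKind.INS
    if kind is MutationKind.INS:
        if pos > len(wt) + 1:
            raise ValueError(f"insertion position {pos} beyond n+1={len(wt) + 1}")
    else:
        if pos > len(wt):
            raise ValueError(f"position {pos} beyond sequence length {len(wt)}")
        actual = wt[pos - 1]
        if actual != wt_base:
            raise ValueError(
                f"{text!r}: position {pos} holds {actual}, not {wt_base}"
            )
    return Mutation(kind, pos, wt_base=wt_base, new_base=new)


@dataclass(frozen=True)
class EditScript:
    """A set of mutations acting on pairwise-distinct positions."""

    mutations: tuple[Mutation, ...]

    def __init__(self, mutations: Iterable[Mutation]) -> None:
        ordered = tuple(sorted(mutations, key=lambda m: (m.position, m.kind.value)))
        positions = [m.position for m in ordered]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in edit script: {positions}")
        object.__setattr__(self, "mutations", ordered)

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    @property
    def name(self) -> str:
        return format_set_name(self)

    def count(self, kind: MutationKind) -> int:
        return sum(1 for m in self.mutations if m.kind is kind)


def format_set_name(e: EditScript) -> str:
    """Components joined by "-" in ascending position order, e.g. "29G-C39-A50-G77"."""
    return "-".join(format_mutation_name(m) for m in e.mutations)


def parse_set_name(text: str, wt: str) -> EditScript:
    return EditScript(parse_mutation_name(part, wt) for part in text.split("-"))


def apply_edit_script(wt: str, e: EditScript) -> str:
    """Apply an edit script to a wild-type sequence.

    Edits are anchored at wild-type coordinates and applied in descending
    position order, so that no edit shifts another's anchor.  The mutant
    length is n - #DEL + #INS.
    """
    chars = list(wt)
    n = len(wt)
    for m in sorted(e.mutations, key=lambda m: m.position, reverse=True):
        if m.kind is MutationKind.INS:
            if m.position > n + 1:
                raise ValueError(f"insertion position {m.position} beyond n+1")
            chars.insert(m.position - 1, m.new_base)
            continue
        if m.position > n:
            raise ValueError(f"position {m.position} beyond sequence length {n}")
        if wt[m.position - 1] != m.wt_base:
            raise ValueError(
                f"wt base mismatch at {m.position}: sequence has "
                f"{wt[m.position - 1]}, mutation records {m.wt_base}"
            )
        if m.kind is MutationKind.SUB:
            chars[m.position - 1] = m.new_base
        else:  # DEL
            del chars[m.position - 1]
    return "".join(chars)
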