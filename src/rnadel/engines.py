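"""Folding engines: MFE structure and bounded-energy suboptimal ensembles.

Two engines sit behind one contract:

* ``thermodynamic`` — the ViennaRNA nearest-neighbor model.  MFE folding goes
  through the ``RNA`` Python bindings; suboptimal enumeration streams from the
  ``RNAsubopt`` executable so that ensembles of hundreds of thousands of
  structures never reside in memory.  Energies are kcal/mol.
* ``simple`` — a pair-counting model in which the energy of (w, S) is minus
  the number of canonical pairs (AU, CG, GU) in S, with a minimum hairpin
  loop of 3 unpaired bases for steric realism.  The MFE is computed by a
  Nussinov-style dynamic program; suboptimal enumeration is exact (every
  structure within ``e_range`` pairs of the maximum) and streamed from a
  budgeted backtracking of the DP table.

The simple engine makes the whole pipeline runnable and exactly testable
without any thermodynamic parameters; the pipeline never compares energies
across engines.
"""

from __future__ import annotations

import itertools
import random
import shutil
import subprocess
from dataclasses import dataclass
from functools import cached_property, lru_cache
from typing import Iterator

import numpy as np

from .structures import (
    SecondaryStructure,
    can_pair,
    clean_sequence,
    parse_dot_bracket,
)

MIN_HAIRPIN = 3
ENUMERATION_LIMIT = 25


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class FoldResult:
    """A folded structure with its energy.

    ``dot_bracket`` is the primary representation (cheap when streaming huge
    ensembles); the parsed :class:`SecondaryStructure` is built lazily.
    Energy is kcal/mol for the thermodynamic engine and the integer
    -(canonical pair count) for the simple engine.
    """

    dot_bracket: str
    energy: float

    @cached_property
    def structure(self) -> SecondaryStructure:
        return parse_dot_bracket(self.dot_bracket)


@dataclass(frozen=True)
class EngineConfig:
    """Engine selection plus the suboptimal energy band ``e_range``.

    ``e_range`` is kcal/mol above the MFE for the thermodynamic engine and an
    integer pair-count slack for the simple engine.
    """

    engine_kind: str = "thermodynamic"
    e_range: float = 0.0

    def __post_init__(self) -> None:
        if self.engine_kind not in ("thermodynamic", "simple"):
            raise EngineError(f"unknown engine kind {self.engine_kind!r}")
        if self.e_range < 0:
            raise EngineError("e_range must be >= 0")


class SimpleEngine:
    """Canonical-pair-maximizing folding under the pair-counting model."""

    name = "simple"

    def __init__(self, min_hairpin: int = MIN_HAIRPIN) -> None:
        self.min_hairpin = min_hairpin

    @property
    def version(self) -> str:
        return f"pair-counting (min hairpin {self.min_hairpin})"

    def _tables(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Max-pair DP table E[i, j] (1-based, inclusive) and pairability."""
        return _simple_tables(seq, self.min_hairpin)
    def fold_mfe(self, seq: str) -> FoldResult:
        """Deterministic maximum-pair fold.

        Traceback rule: the leftmost undecided position pairs with its
        nearest admissible partner whenever some optimal completion pairs it.
        """
        seq = clean_sequence(seq)
        n = len(seq)
        dp, canp = self._tables(seq)
        pairs: list[tuple[int, int]] = []
        stack = [(1, n)]
        while stack:
            i, j = stack.pop()
            while i < j:
                if dp[i, j] == dp[i + 1, j]:
                    i += 1
                    continue
                for k in range(i + self.min_hairpin + 1, j + 1):
                    if canp[i, k] and dp[i, j] == 1 + dp[i + 1, k - 1] + dp[k + 1, j]:
                        pairs.append((i, k))
                        if k + 1 < j:
                            stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        break
        structure = SecondaryStructure.from_pairs(n, pairs)
        return FoldResult(structure.to_dot_bracket(), -float(len(pairs)))

    def subopt(
        self,
        seq: str,
        e_range: float,
        rng: random.Random | None = None,
    ) -> Iterator[FoldResult]:
        """Stream every structure with pair count >= max - e_range.

        Backtracks the DP table carrying the remaining pair deficit; branches
        that cannot stay within the deficit are pruned, so the enumeration is
        output-sensitive.  When *rng* is given the branch order is shuffled at
        every decision point, so that a truncated (capped) consumption of the
        stream still samples diverse structures; without it the order is
        deterministic.  The stream is exhaustive whenever it is consumed in
        full — callers enumerating small sequences get the exact ensemble.
        """
        seq = clean_sequence(seq)
        n = len(seq)
        dp, canp = self._tables(seq)
        slack = int(e_range)
        chars = ["."] * n

        def gen(intervals: tuple, budget: int, npairs: int) -> Iterator[FoldResult]:
            if not intervals:
                yield FoldResult("".join(chars), -float(npairs))
                return
            (i, j), rest = intervals[0], intervals[1:]
            if i >= j:
                for k in range(i, j + 1):
                    chars[k - 1] = "."
                yield from gen(rest, budget, npairs)
                return
            options: list[tuple[int, int]] = []  # (k or 0 for unpaired, cost)
            cost_unpaired = int(dp[i, j] - dp[i + 1, j])
            if cost_unpaired <= budget:
                options.append((0, cost_unpaired))
            for k in range(i + self.min_hairpin + 1, j + 1):
                if canp[i, k]:
                    cost = int(dp[i, j] - (1 + dp[i + 1, k - 1] + dp[k + 1, j]))
                    if cost <= budget:
                        options.append((k, cost))
            if rng is not None:
                rng.shuffle(options)
            for k, cost in options:
                if k == 0:
                    chars[i - 1] = "."
                    yield from gen(((i + 1, j),) + rest, budget - cost, npairs)
                else:
                    chars[i - 1] = "("
                    chars[k - 1] = ")"
                    yield from gen(
                        ((i + 1, k - 1), (k + 1, j)) + rest,
                        budget - cost,
                        npairs + 1,
                    )

        yield from gen(((1, n),), slack, 0)

    def subopt_sample(
        self,
        seq: str,
        e_range: float,
        rng: random.Random,
        chunk: int = 5,
    ) -> Iterator[FoldResult]:
        """Endless stream of near-optimal structures for capped consumption.

        The exact enumeration of :meth:`subopt` is depth-first, so a
        truncated prefix of it explores only one corner of a large ensemble.
        This sampler instead restarts the randomized enumeration with a fresh
        sub-seed every *chunk* structures, which spreads a capped sample
        across the whole energy band.  Structures may repeat across restarts;
        the stream never terminates on its own, so consumers must cap it.
        """
        while True:
            sub_rng = random.Random(rng.randrange(2 ** 31))
            yield from itertools.islice(self.subopt(seq, e_range, rng=sub_rng), chunk)


@lru_cache(maxsize=8)
def _simple_tables(seq: str, min_hairpin: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(seq)
    canp = np.zeros((n + 2, n + 2), dtype=bool)
    for i in range(1, n + 1):
        for j in range(i + min_hairpin + 1, n + 1):
            canp[i, j] = can_pair(seq[i - 1], seq[j - 1])
    dp = np.zeros((n + 2, n + 2), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = dp[i + 1, j]
            ks = np.nonzero(canp[i, i:j + 1])[0] + i
            if ks.size:
                vals = 1 + dp[i + 1, ks - 1] + dp[ks + 1, j]
                best = max(best, int(vals.max()))
            dp[i, j] = best
    return dp, canp


class ViennaEngine:
    """Adapter for the ViennaRNA thermodynamic model at default parameters."""

    name = "thermodynamic"

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise EngineError(
                "the thermodynamic engine requires the ViennaRNA Python "
                "bindings (module 'RNA'); install ViennaRNA or use the "
                "'simple' engine"
            ) from exc
        self._rna = __import__("RNA")

    @property
    def version(self) -> str:
        return f"ViennaRNA {self._rna.__version__}"

    def fold_mfe(self, seq: str) -> FoldResult:
        seq = clean_sequence(seq)
        db, energy = self._rna.fold_compound(seq).mfe()
        return FoldResult(db, round(float(energy), 2))

    def subopt(
        self,
        seq: str,
        e_range: float,
        rng: random.Random | None = None,
    ) -> Iterator[FoldResult]:
        """Stream all structures within ``e_range`` kcal/mol of the MFE.

        Runs ``RNAsubopt`` as a subprocess and yields line by line, tolerating
        both "structure energy" output formats and trailing whitespace.
        """
        seq = clean_sequence(seq)
        exe = shutil.which("RNAsubopt")
        if exe is None:  # pragma: no cover - environment dependent
            raise EngineError("RNAsubopt executable not found on PATH")
        proc = subprocess.Popen(
            [exe, "-e", f"{float(e_range):g}"],
            stdin=subprocess.PIPE,
            stdout=subprocess.PIPE,
            text=True,
        )
        assert proc.stdin is not None and proc.stdout is not None
        proc.stdin.write(seq + "\n")
        proc.stdin.close()
        try:
            for line in proc.stdout:
                fields = line.split()
                if not fields or fields[0][0] not in ".()":
                    continue  # header line echoing the sequence
                yield FoldResult(fields[0], float(fields[1]))
        finally:
            proc.stdout.close()
            proc.wait()

    def subopt_sample(
        self,
        seq: str,
        e_range: float,
        rng: random.Random,
        chunk: int = 100,
    ) -> Iterator[FoldResult]:
        """Endless seeded stream of Boltzmann-sampled structures within
        ``e_range`` kcal/mol of the MFE, for capped consumption.

        The complete ``RNAsubopt`` enumeration of a weakly structured
        sequence can run to hundreds of millions of structures; stochastic
        backtracking from the partition function draws representative
        structures from the same energy band instead.  Samples outside the
        band are discarded; the stream never terminates on its own.
        """
        seq = clean_sequence(seq)
        RNA = self._rna
        md = RNA.md()
        md.uniq_ML = 1
        RNA.init_rand(rng.randrange(2 ** 31))
        fc = RNA.fold_compound(seq, md)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        cutoff = mfe + e_range + 1e-6
        while True:
            for db in fc.pbacktrack(chunk):
                energy = round(fc.eval_structure(db), 2)
                if energy <= cutoff:
                    yield FoldResult(db, energy)


def get_engine(kind: str):
    """Engine factory; raises a configuration error naming a missing engine."""
    if kind == "simple":
        return SimpleEngine()
    if kind == "thermodynamic":
        return ViennaEngine()
    raise EngineError(f"unknown engine kind {kind!r}")


def fold_mfe(seq: str, cfg: EngineConfig) -> FoldResult:
    return get_engine(cfg.engine_kind).fold_mfe(seq)


def subopt_fold(seq: str, cfg: EngineConfig) -> Iterator[FoldResult]:
    return get_engine(cfg.engine_kind).subopt(seq, cfg.e_range)


def enumerate_all_structures(
    n: int, min_hairpin: int = MIN_HAIRPIN
) -> Iterator[SecondaryStructure]:
    """Yield every nested structure on n positions with hairpin loops
    >= min_hairpin, exactly once.  Exponential; guarded at n <= 25."""
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"exhaustive enumeration refused for n={n} > {ENUMERATION_LIMIT}"
        )

    def gen(i: int, j: int) -> Iterator[frozenset]:
        # structures over positions i..j
        if i > j:
            yield frozenset()
            return
        # position i unpaired
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + min_hairpin + 1, j + 1):
            for inside in gen(i + 1, k - 1):
                for after in gen(k + 1, j):
                    yield inside | after | {(i, k)}

    for pairs in gen(1, n):
        yield SecondaryStructure(n, pairs)
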