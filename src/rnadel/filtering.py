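"""Two-stage diversity filter over the suboptimal ensemble.

Stage 1 drops every suboptimal structure whose distance from the optimal
structure does not exceed ``dist1`` (structures "similar to the optimal one").
Stage 2 sorts the survivors by distance from the optimal structure,
descending, and scans greedily, keeping a structure iff its distance to every
already-kept representative exceeds ``dist2``.  Each kept representative is
thus the most distant member of its cluster of similar structures, and
distant from all other representatives.

Distances are positionwise dot-bracket (Hamming) distances, the kernel that
reproduces the bundled benchmark's reference values; thresholds are strict
(a structure at exactly the threshold distance counts as "close" and is
removed), which reproduces the benchmark's representative count of six.

Stage 1 is streaming: the ensemble is consumed one structure at a time and
only survivors are buffered for sorting, so multi-hundred-thousand-structure
ensembles never reside in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .engines import FoldResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    dist1: int
    dist2: int

    def __post_init__(self) -> None:
        if self.dist1 < 0 or self.dist2 < 0:
            raise ValueError("distance thresholds must be non-negative")


def default_filter_params(n: int) -> FilterParams:
    """Suggested thresholds: about 30% of the sequence length for both."""
    return FilterParams(round(0.30 * n), round(0.30 * n))


def default_e_range(n: int) -> int:
    """Suggested suboptimal energy band: about 15% of the sequence length."""
    return round(0.15 * n)


@dataclass(frozen=True)
class Representative:
    fold: FoldResult
    distance: int


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def filter_suboptimals(
    opt: FoldResult | str,
    subs: Iterable[FoldResult],
    params: FilterParams,
) -> list[Representative]:
    """Reduce an ensemble to distant, mutually dissimilar representatives.

    Returns representatives in descending order of distance from the optimal
    structure (ties broken by lexicographic dot-bracket order).
    """
    opt_db = opt if isinstance(opt, str) else opt.dot_bracket
    opt_arr = np.frombuffer(opt_db.encode(), dtype=np.uint8)
    survivors: list[tuple[int, str, FoldResult]] = []
    total = 0
    for fr in subs:
        total += 1
        if len(fr.dot_bracket) != len(opt_db):
            raise ValueError(
                f"structure length {len(fr.dot_bracket)} != optimal {len(opt_db)}"
            )
        d = _hamming(np.frombuffer(fr.dot_bracket.encode(), dtype=np.uint8), opt_arr)
        if d > params.dist1:
            survivors.append((d, fr.dot_bracket, fr))
    logger.info(
        "stage 1: kept %d of %d suboptimal structures (dist1=%d)",
        len(survivors), total, params.dist1,
    )
    survivors.sort(key=lambda t: (-t[0], t[1]))
    kept: list[Representative] = []
    kept_arrays: list[np.ndarray] = []
    for d, db, fr in survivors:
        arr = np.frombuffer(db.encode(), dtype=np.uint8)
        if all(_hamming(arr, prev) > params.dist2 for prev in kept_arrays):
            kept.append(Representative(fr, d))
            kept_arrays.append(arr)
    logger.info(
        "stage 2: kept %d representatives (dist2=%d)", len(kept), params.dist2
    )
    return kept
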