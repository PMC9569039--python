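"""End-to-end prediction pipeline.

fold -> suboptimal ensemble -> two-stage diversity filter -> per-representative
candidate mutations -> randomized M-set assembly under quotas -> refolding
validation -> ranked output.
"""

from __future__ import annotations

import itertools
import logging
import random
import time
from dataclasses import dataclass, field, replace

from .assembly import (
    AssemblyConfig,
    MutationRecord,
    assemble_sets,
    validate_and_rank,
)
from .candidates import collect_candidates
from .engines import get_engine
from .filtering import (
    FilterParams,
    Representative,
    default_e_range,
    default_filter_params,
    filter_suboptimals,
)
from .structures import MAX_PIPELINE_LENGTH, MutationKind, clean_sequence

logger = logging.getLogger(__name__)


class NoRepresentativesError(RuntimeError):
    """No suboptimal structure survived filtering; raise e_range or lower dist1."""


@dataclass(frozen=True)
class RunConfig:
    """All user-facing parameters of a prediction run.

    ``dist1``/``dist2`` (filter thresholds) default to round(0.30 * n) and
    ``e_range`` (suboptimal energy band) to round(0.15 * n); the validation
    threshold defaults to ``dist1`` so that one notion of "deleterious"
    applies throughout.  ``max_subopt`` optionally caps how many suboptimal
    structures are drawn from the engine's stream (needed for the simple
    engine on long sequences, where the exact ensemble is astronomically
    large); ``None`` consumes the full stream.
    """

    sequence: str
    dist1: int | None = None
    dist2: int | None = None
    e_range: float | None = None
    m: int = 2
    n_results: int = 100
    allowed: frozenset[MutationKind] = frozenset(MutationKind)
    seed: int = 0
    engine: str = "thermodynamic"
    validation_threshold: int | None = None
    max_subopt: int | None = None
    attack_size1_stems: bool = False


@dataclass
class RunResult:
    records: list[MutationRecord]
    representatives: list[Representative]
    wt_fold: "FoldResult"
    metadata: dict


def run_pipeline(cfg: RunConfig) -> RunResult:
    seq = clean_sequence(cfg.sequence, max_length=MAX_PIPELINE_LENGTH)
    n = len(seq)
    fp_default = default_filter_params(n)
    dist1 = fp_default.dist1 if cfg.dist1 is None else cfg.dist1
    dist2 = fp_default.dist2 if cfg.dist2 is None else cfg.dist2
    e_range = default_e_range(n) if cfg.e_range is None else cfg.e_range
    threshold = dist1 if cfg.validation_threshold is None else cfg.validation_threshold

    engine = get_engine(cfg.engine)
    t0 = time.time()
    wt_fold = engine.fold_mfe(seq)
    logger.info("wild-type MFE: %s (%.2f)", wt_fold.dot_bracket, wt_fold.energy)

    rng = random.Random(cfg.seed)
    if cfg.max_subopt is not None and hasattr(engine, "subopt_sample"):
        # capped consumption of an exact depth-first enumeration explores only
        # one corner of a large ensemble; sample restarts instead
        stream = itertools.islice(
            engine.subopt_sample(seq, e_range, rng=rng), cfg.max_subopt
        )
    elif cfg.max_subopt is not None:
        stream = itertools.islice(engine.subopt(seq, e_range, rng=rng), cfg.max_subopt)
    else:
        stream = engine.subopt(seq, e_range, rng=rng)
    reps = filter_suboptimals(wt_fold, stream, FilterParams(dist1, dist2))
    if not reps:
        raise NoRepresentativesError(
            "no suboptimal structure survived filtering; "
            "raise e_range or lower dist1"
        )

    candidates_by_sub = [
        collect_candidates(
            seq, wt_fold.structure, rep.fold.structure, cfg.allowed,
            attack_size1_stems=cfg.attack_size1_stems,
        )
        for rep in reps
    ]
    acfg = AssemblyConfig(
        m=cfg.m,
        n_results=cfg.n_results,
        allowed=frozenset(cfg.allowed),
        seed=cfg.seed,
        validation_threshold=threshold,
    )
    scripts = assemble_sets(candidates_by_sub, acfg)
    records = validate_and_rank(scripts, seq, wt_fold.structure, acfg, engine)
    metadata = {
        "sequence": seq,
        "n": n,
        "dist1": dist1,
        "dist2": dist2,
        "e_range": e_range,
        "m": cfg.m,
        "n_results": cfg.n_results,
        "allowed": sorted(k.value for k in cfg.allowed),
        "seed": cfg.seed,
        "engine": engine.name,
        "engine_version": engine.version,
        "validation_threshold": threshold,
        "max_subopt": cfg.max_subopt,
        "n_representatives": len(reps),
        "n_scripts_assembled": len(scripts),
        "wt_energy": wt_fold.energy,
        "runtime_s": round(time.time() - t0, 3),
    }
    return RunResult(records, reps, wt_fold, metadata)
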