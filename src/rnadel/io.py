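"""FASTA input and TSV/JSON result persistence."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .assembly import MutationRecord
from .structures import clean_sequence, parse_dot_bracket, parse_set_name

logger = logging.getLogger(__name__)

TSV_COLUMNS = ("name", "energy_kcal_mol", "bp_distance", "dot_bracket", "source_subopt")


def read_fasta_single(path: str | Path) -> str:
    """Read one RNA sequence from a FASTA file (first record; extra records
    are warned about).  T is normalized to U."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
    return clean_sequence(str(records[0].seq))


def write_results_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                f"{rec.name}\t{rec.energy:.2f}\t{rec.distance}\t"
                f"{rec.mutant_structure.to_dot_bracket()}\t{rec.source_sub}\n"
            )


def save_results(
    records: Sequence[MutationRecord], metadata: dict, path: str | Path
) -> None:
    """Persist a result set (records + run metadata) as JSON."""
    payload = {
        "metadata": metadata,
        "records": [
            {
                "name": rec.name,
                "mutant_seq": rec.mutant_seq,
                "dot_bracket": rec.mutant_structure.to_dot_bracket(),
                "energy": rec.energy,
                "distance": rec.distance,
                "source_sub": rec.source_sub,
            }
            for rec in records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_results(path: str | Path) -> tuple[list[MutationRecord], dict]:
    """Inverse of :func:`save_results`."""
    payload = json.loads(Path(path).read_text())
    metadata = payload["metadata"]
    wt = metadata["sequence"]
    records = []
    for entry in payload["records"]:
        script = parse_set_name(entry["name"], wt)
        records.append(
            MutationRecord(
                name=entry["name"],
                script=script,
                mutant_seq=entry["mutant_seq"],
                mutant_structure=parse_dot_bracket(entry["dot_bracket"]),
                energy=entry["energy"],
                distance=entry["distance"],
                source_sub=entry["source_sub"],
            )
        )
    return records, metadata
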