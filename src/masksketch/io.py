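"""FASTA input, BED/TSV/JSON output and provenance helpers."""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .schemes import Sketch
from .sequence import DNA, Sequence, SequenceError


def read_fasta(
    path, n_policy: str = "reject", alphabet: str = DNA
) -> list[tuple[str, Sequence]]:
    """Read a (possibly multi-record) FASTA file.

    n_policy:
        ``"reject"`` — any symbol outside the alphabet raises a
        :class:`SequenceError` naming the record and offset.
        ``"split"`` — records are split at runs of out-of-alphabet
        symbols; parts are named ``<name>:<start>-<end>`` (0-based,
        half-open, coordinates in the original record).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out: list[tuple[str, Sequence]] = []
    allowed = set(alphabet)
    for rec in records:
        raw = str(rec.seq).upper()
        if not raw:
            raise SequenceError(f"record {rec.id!r} is empty")
        bad = next((i for i, ch in enumerate(raw) if ch not in allowed), None)
        if bad is None:
            out.append((rec.id, Sequence(raw, alphabet=alphabet)))
        elif n_policy == "reject":
            raise SequenceError(
                f"record {rec.id!r}: illegal symbol {raw[bad]!r} at offset {bad} "
                f"(use n_policy='split' to split at such runs)"
            )
        elif n_policy == "split":
            for m in re.finditer(f"[{alphabet}]+", raw):
                out.append(
                    (f"{rec.id}:{m.start()}-{m.end()}",
                     Sequence(m.group(0), alphabet=alphabet))
                )
        else:
            raise ValueError(f"unknown n_policy {n_policy!r}")
    return out


def write_fasta(path, records: list[tuple[str, Sequence]], width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            s = seq.symbols
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_sketch_bed(path, name: str, sketch: Sketch, append: bool = False) -> None:
    """BED3, 0-based half-open: one line per selected k-mer."""
    mode = "a" if append else "w"
    with Path(path).open(mode) as fh:
        for i in sketch.indices:
            fh.write(f"{name}\t{i}\t{i + sketch.k}\n")


def write_metrics_tsv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable config, for provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_json(path, obj: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
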