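"""FASTA/FASTQ/TSV readers and writers.

Simulated reads carry their truth label both as a ``/lab=<0|1>`` suffix on
the read name and in a sidecar two-column TSV (``read_id<TAB>label``), so
labels survive tools that strip FASTQ comments. Genome FASTA is written with
60-column wrapping. Coordinates in manifests are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .simulate import LabeledRead, SyntheticGenome

_LABEL_SUFFIX = "/lab="


def write_fasta(genome: SyntheticGenome, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{genome.identifier}\n")
        seq = genome.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[SyntheticGenome]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [SyntheticGenome(identifier=r.id, sequence=str(r.seq).upper()) for r in records]


def write_fastq(reads: Iterable[LabeledRead], path: str | Path, label_in_name: bool = True) -> int:
    """Write reads as FASTQ; returns the number of records written."""
    path = Path(path)
    n = 0
    with path.open("w") as fh:
        for read in reads:
            name = read.read_id
            if label_in_name and read.label is not None:
                name = f"{name}{_LABEL_SUFFIX}{read.label}"
            qual = read.quality or ("I" * len(read.sequence))
            fh.write(f"@{name}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[LabeledRead]:
    """Parse FASTQ; a ``/lab=<0|1>`` name suffix is decoded into the label."""
    reads: list[LabeledRead] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        name = rec.id
        label: int | None = None
        if _LABEL_SUFFIX in name:
            name, _, tail = name.rpartition(_LABEL_SUFFIX)
            try:
                label = int(tail)
            except ValueError as exc:
                raise ValueError(f"record {i}: malformed label suffix {tail!r}") from exc
            if label not in (0, 1):
                raise ValueError(f"record {i}: label must be 0 or 1, got {label}")
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations.get("phred_quality", [])
        )
        reads.append(
            LabeledRead(
                read_id=name, sequence=str(rec.seq).upper(), label=label, quality=qual or None
            )
        )
    return reads


def write_label_tsv(labels: dict[str, int] | Iterable[tuple[str, int]], path: str | Path) -> None:
    items = labels.items() if isinstance(labels, dict) else labels
    with Path(path).open("w") as fh:
        for rid, lab in items:
            fh.write(f"{rid}\t{lab}\n")


def read_label_tsv(path: str | Path) -> dict[str, int]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    labels: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_score_tsv(rows: Iterable[tuple[str, int, float]], path: str | Path) -> None:
    """Per-read ``read_id<TAB>predicted_label<TAB>score`` table."""
    with Path(path).open("w") as fh:
        fh.write("read_id\tlabel\tscore\n")
        for rid, lab, score in rows:
            fh.write(f"{rid}\t{lab}\t{score:.6g}\n")


def write_manifest(params: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
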