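"""Confusion-matrix metrics, alignment-derived truth labels and redundancy.

Polarity convention
-------------------
Although the classifier emits label 1 for erroneous reads, the POSITIVE class
of every metric here is the ERROR-FREE read (label 0):

    TP = error-free reads predicted error-free
    FP = erroneous reads predicted error-free
    FN = error-free reads predicted erroneous
    TN = erroneous reads predicted erroneous

This inversion is pinned in :func:`confusion` and nowhere else. Metrics with
a zero denominator are reported as ``None`` (absent), never as 0.

Truth labels for real reads come from alignments: a read is deemed correct
(label 0) when its primary alignment covers at least T bases of the read
(sum of CIGAR M/=/X lengths); unmapped reads are erroneous.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Accuracy/precision/recall/F1/MCC and optionally ROC-AUC.

    A ``None`` value means the metric was undefined for these counts (zero
    denominator) or, for ROC-AUC, that no scores were supplied.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    mcc: float | None
    roc_auc: float | None = None
    counts: ConfusionCounts | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            k: v for k, v in asdict(self).items() if k != "counts"
        }
        if self.counts is not None:
            payload["counts"] = asdict(self.counts)
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _check_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(np.int64)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with the error-free read (label 0) as positive class."""
    t = _check_binary(y_true, "y_true")
    p = _check_binary(y_pred, "y_pred")
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    return ConfusionCounts(
        tp=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 1) & (p == 0)).sum()),
        fn=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 1) & (p == 1)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return None
    return num / den


def metrics(
    counts: ConfusionCounts,
    y_true: Sequence[int] | None = None,
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Metric suite from confusion counts, plus ROC-AUC when scores given.

    Scores are expected on the classifier's native scale (larger = more
    likely erroneous); they are negated internally so that ROC-AUC, like the
    other metrics, treats the error-free read as the positive class.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    accuracy = _ratio(tp + tn, counts.total, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        logger.warning("F1 undefined")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    roc_auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required to compute ROC-AUC from scores")
        t = _check_binary(y_true, "y_true")
        if len(np.unique(t)) == 2:
            # positive class = error-free (0); native scores rank class 1 high
            roc_auc = float(roc_auc_score((t == 0).astype(int), -np.asarray(scores, dtype=float)))
        else:
            logger.warning("ROC-AUC undefined: single-class truth")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        roc_auc=roc_auc,
        counts=counts,
    )


def evaluate_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Confusion + metrics in one call."""
    return metrics(confusion(y_true, y_pred), y_true=y_true, scores=scores)


# ---------------------------------------------------------------------------
# Alignment-based truth labeling
# ---------------------------------------------------------------------------

# CIGAR operations consuming both read and reference: M(0), =(7), X(8)
_ALIGNED_OPS = {0, 7, 8}


@dataclass(frozen=True)
class AlignmentTruthSpec:
    """Threshold T on the per-read aligned-base count; unmapped = erroneous."""

    threshold: int

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold}")


def aligned_base_count(record: pysam.AlignedSegment, use_as_tag: bool = False) -> int:
    """Bases of the read aligned to the reference.

    Default: sum of CIGAR M/=/X operation lengths (insertions and clips are
    excluded). ``use_as_tag`` reads the aligner's AS tag instead. Unmapped
    records count 0.
    """
    if record.is_unmapped:
        return 0
    if use_as_tag:
        return int(record.get_tag("AS"))
    cigar = record.cigartuples
    if cigar is None:
        raise ValueError(f"record {record.query_name!r} is mapped but has no CIGAR")
    return sum(length for op, length in cigar if op in _ALIGNED_OPS)


def read_primary_alignments(
    sam_path: str | Path, use_as_tag: bool = False
) -> dict[str, int]:
    """Per-read aligned-base count from the primary alignments of a SAM file.

    Secondary and supplementary records are ignored; a second primary record
    for the same read id is an error.
    """
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if name in counts:
                raise ValueError(f"duplicate primary alignment for read {name!r}")
            counts[name] = aligned_base_count(rec, use_as_tag=use_as_tag)
    return counts


def label_from_alignment(
    aligned_bases: dict[str, int], spec: AlignmentTruthSpec
) -> dict[str, int]:
    """Truth labels: 0 (correct) iff aligned bases >= T, else 1 (erroneous)."""
    return {
        rid: 0 if n >= spec.threshold else 1 for rid, n in aligned_bases.items()
    }


def duplicate_read_fraction(sequences: Iterable[str], include_revcomp: bool = False) -> tuple[int, float]:
    """Exact-duplicate count and percentage among read sequences.

    A duplicate is any read beyond the first occurrence of its exact sequence
    (optionally also matching the reverse complement of an earlier read).
    """
    from .simulate import reverse_complement

    seqs = list(sequences)
    if not seqs:
        raise ValueError("duplicate analysis requires at least one read")
    if not include_revcomp:
        distinct = len(set(seqs))
    else:
        seen: set[str] = set()
        distinct = 0
        for s in seqs:
            if s in seen or reverse_complement(s) in seen:
                continue
            seen.add(s)
            distinct += 1
    dup = len(seqs) - distinct
    return dup, 100.0 * dup / len(seqs)
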