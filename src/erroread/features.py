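"""k-mer tokenization and TF-IDF feature extraction for sequencing reads.

Reads are treated as documents and their k-mers as terms. For read r_i and
k-mer s_ij with occurrence count f_ij,

    TF_ij  = f_ij / (number of k-mer windows in r_i)
    IDF_ij = log(N / N_ij)

where N is the corpus size and N_ij the number of reads containing s_ij at
least once. The feature value is TF_ij * IDF_ij. No smoothing and no row
normalization are applied by default; the ``smooth_l2`` dialect (add-one
document-frequency smoothing plus L2 row normalization, the convention of
common text vectorizers) is available for cross-checking.

Internally k-mers are packed two bits per base into int64 codes (k <= 31),
so matrices stay sparse and the vocabulary stays compact even at k = 15,
where the term space has 4^15 ≈ 10^9 possible columns. Code order equals
lexicographic k-mer order (A<C<G<T map to 0<1<2<3), so column indices are
deterministic and independent of corpus input order.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .simulate import LabeledRead

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")

# ASCII -> 2-bit base code; 255 marks any non-ACGT character
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

MAX_K = 31


def _encode_read(sequence: str, k: int) -> np.ndarray:
    """int64 codes of all valid k-mer windows, in window order.

    Windows containing a non-ACGT character are dropped. Returns an empty
    array when k exceeds the read length.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}, got {k}")
    base = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    L = base.size
    if k > L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(base, k)
    valid = ~(windows == 255).any(axis=1)
    pow4 = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    codes = windows[valid].astype(np.int64) @ pow4
    return codes


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _kmer_to_code(term: str, k: int) -> int:
    if len(term) != k:
        raise ValueError(f"term {term!r} is not a {k}-mer")
    code = 0
    for c in term.upper():
        if c not in _VALID:
            raise ValueError(f"term {term!r} contains a non-ACGT character")
        code = (code << 2) | "ACGT".index(c)
    return code


@dataclass
class KmerProfile:
    """Bag of k-mers of one read.

    ``total_positions`` counts the valid sliding windows (L - k + 1 minus any
    window containing a non-ACGT character); it is the TF denominator.
    """

    read_id: str
    k: int
    term_counts: dict[str, int]
    total_positions: int


def extract_kmers(sequence: str, k: int, read_id: str = "") -> KmerProfile:
    """Slide a window of length k along the read; skip windows with non-ACGT.

    Matching is case-insensitive. ``k`` larger than the read yields an empty
    profile (zero windows), which downstream becomes an all-zero feature row.
    """
    codes = _encode_read(sequence, k)
    counts = Counter(_code_to_kmer(int(c), k) for c in codes)
    return KmerProfile(
        read_id=read_id, k=k, term_counts=dict(counts), total_positions=int(codes.size)
    )


@dataclass
class Vocabulary:
    """k-mer -> column map with per-term document frequencies.

    Columns are ordered by packed k-mer code, i.e. lexicographically by
    k-mer, so the map does not depend on corpus input order. ``doc_freq[j]``
    is N_ij for column j; ``corpus_size`` is N, the number of fitted reads.
    """

    k: int
    codes: np.ndarray  # sorted int64 k-mer codes, one per column
    doc_freq: np.ndarray
    corpus_size: int
    log_base: str = "e"  # "e" (natural log) or "10"

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def terms(self) -> dict[str, int]:
        """Ordered k-mer -> column index map (materialized on demand)."""
        return {_code_to_kmer(int(c), self.k): j for j, c in enumerate(self.codes)}

    def column_of(self, term: str) -> int | None:
        code = _kmer_to_code(term, self.k)
        j = int(np.searchsorted(self.codes, code))
        if j < len(self.codes) and self.codes[j] == code:
            return j
        return None

    def __contains__(self, term: str) -> bool:
        return self.column_of(term) is not None

    def idf(self, term: str) -> float:
        """IDF = log(N / N_ij); 0 for a term present in every fitted read."""
        j = self.column_of(term)
        if j is None:
            raise KeyError(f"term {term!r} not in vocabulary")
        x = self.corpus_size / self.doc_freq[j]
        return math.log10(x) if self.log_base == "10" else math.log(x)

    def idf_vector(self, smooth: bool = False) -> np.ndarray:
        """Per-column IDF; ``smooth`` applies the 1 + ln((1+N)/(1+df))
        convention of common vectorizers."""
        df = self.doc_freq.astype(float)
        if smooth:
            return 1.0 + np.log((1.0 + self.corpus_size) / (1.0 + df))
        if self.log_base == "10":
            return np.log10(self.corpus_size / df)
        return np.log(self.corpus_size / df)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#k={self.k} N={self.corpus_size}\n")
            for j, c in enumerate(self.codes):
                fh.write(f"{_code_to_kmer(int(c), self.k)}\t{j}\t{int(self.doc_freq[j])}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError(f"malformed vocabulary header: {header!r}")
            fields = dict(item.split("=") for item in header[1:].split())
            k = int(fields["k"])
            n = int(fields["N"])
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        order = sorted(range(len(rows)), key=lambda i: int(rows[i][1]))
        codes = np.array([_kmer_to_code(rows[i][0], k) for i in order], dtype=np.int64)
        doc_freq = np.array([int(rows[i][2]) for i in order], dtype=np.int64)
        if not np.all(np.diff(codes) > 0):
            raise ValueError("vocabulary columns are not in lexicographic order")
        return cls(k=k, codes=codes, doc_freq=doc_freq, corpus_size=n)


def _sequences(reads: list[LabeledRead] | list[str]) -> list[str]:
    return [r.sequence if isinstance(r, LabeledRead) else r for r in reads]


def build_vocabulary(
    reads: list[LabeledRead] | list[str],
    k: int,
    log_base: str = "e",
) -> Vocabulary:
    """Fit the vocabulary: term union, document frequencies and corpus size.

    Document frequency is presence-based (a term counts once per read no
    matter how many times it occurs).
    """
    seqs = _sequences(reads)
    if not seqs:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    per_read_unique: list[np.ndarray] = []
    for seq in seqs:
        codes = _encode_read(seq, k)
        if codes.size:
            per_read_unique.append(np.unique(codes))
    if not per_read_unique:
        raise ValueError("no read has a valid k-mer window at this k")
    allcodes = np.concatenate(per_read_unique)
    codes, doc_freq = np.unique(allcodes, return_counts=True)
    return Vocabulary(
        k=k,
        codes=codes,
        doc_freq=doc_freq.astype(np.int64),
        corpus_size=len(seqs),
        log_base=log_base,
    )


def term_frequency(profile: KmerProfile, term: str) -> float:
    """TF = f_ij / total windows; 0 for an absent term."""
    if profile.total_positions == 0:
        raise ValueError(
            f"read {profile.read_id!r} has no valid k-mer window; TF undefined"
        )
    return profile.term_counts.get(term.upper(), 0) / profile.total_positions


def inverse_document_frequency(vocab: Vocabulary, term: str) -> float:
    return vocab.idf(term)


def tfidf_transform(
    reads: list[LabeledRead] | list[str],
    vocab: Vocabulary,
    smooth_l2: bool = False,
    distinct_denominator: bool = False,
) -> sp.csr_matrix:
    """TF-IDF matrix of ``reads`` over a fitted vocabulary (CSR, rows in
    input order).

    Terms absent from the vocabulary are dropped (their IDF is undefined), so
    a read sharing no k-mer with the fitted corpus maps to an all-zero row —
    itself a strong signal that the read does not look like the corpus.

    ``distinct_denominator`` divides TF by the number of distinct terms in the
    read instead of the number of windows. ``smooth_l2`` switches to the
    smoothed-IDF + L2-normalized dialect.
    """
    seqs = _sequences(reads)
    k = vocab.k
    idf = vocab.idf_vector(smooth=smooth_l2)
    indptr = np.zeros(len(seqs) + 1, dtype=np.int64)
    chunks_idx: list[np.ndarray] = []
    chunks_dat: list[np.ndarray] = []
    n_zero = 0
    for i, seq in enumerate(seqs):
        codes = _encode_read(seq, k)
        if codes.size == 0:
            n_zero += 1
            indptr[i + 1] = indptr[i]
            continue
        uniq, counts = np.unique(codes, return_counts=True)
        pos = np.searchsorted(vocab.codes, uniq)
        pos = np.minimum(pos, len(vocab.codes) - 1)
        known = vocab.codes[pos] == uniq
        cols = pos[known]
        denom = uniq.size if distinct_denominator else codes.size
        vals = (counts[known] / denom) * idf[cols]
        chunks_idx.append(cols)
        chunks_dat.append(vals)
        indptr[i + 1] = indptr[i] + cols.size
    if n_zero:
        logger.warning(
            "%d read(s) had no valid k-mer window at k=%d; emitted all-zero rows",
            n_zero,
            k,
        )
    indices = (
        np.concatenate(chunks_idx) if chunks_idx else np.empty(0, dtype=np.int64)
    )
    data = np.concatenate(chunks_dat) if chunks_dat else np.empty(0, dtype=float)
    X = sp.csr_matrix((data, indices, indptr), shape=(len(seqs), len(vocab)))
    if smooth_l2:
        norms = sp.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        X = (sp.diags(1.0 / norms) @ X).tocsr()
    return X


def fit_transform(
    reads: list[LabeledRead] | list[str], k: int, **kwargs
) -> tuple[Vocabulary, sp.csr_matrix]:
    """Convenience: fit the vocabulary on ``reads`` and transform them."""
    vocab = build_vocabulary(reads, k)
    return vocab, tfidf_transform(reads, vocab, **kwargs)


def export_mtx(
    X: sp.spmatrix, row_ids: list[str], vocab: Vocabulary, prefix: str | Path
) -> None:
    """Write the matrix as Matrix Market with row/column label sidecars."""
    import scipy.io

    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), X)
    prefix.with_suffix(".rows.txt").write_text("\n".join(row_ids) + "\n")
    cols = [_code_to_kmer(int(c), vocab.k) for c in vocab.codes]
    prefix.with_suffix(".cols.txt").write_text("\n".join(cols) + "\n")
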