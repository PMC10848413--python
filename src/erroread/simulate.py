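"""Synthetic genomes and labeled read simulation.

Emulates a wgsim-style protocol for producing training data for read-error
classification: reads are drawn uniformly from a reference genome, from either
strand, and each base is substituted independently with probability ``e``.
Setting ``e = 0`` yields error-free reads (label 0); ``e = 1`` yields reads in
which every base is wrong (label 1). The read budget for a target fold
coverage follows the Lander–Waterman relation C = L·N/G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CoverageSpec:
    """Fold coverage C, genome length G (bp) and read length L (bp)."""

    coverage: float
    genome_length: int
    read_length: int

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")
        if self.genome_length <= 0:
            raise ValueError(
                f"genome_length must be > 0, got {self.genome_length}"
            )
        if self.read_length <= 0:
            raise ValueError(f"read_length must be > 0, got {self.read_length}")
        if self.read_length > self.genome_length:
            raise ValueError(
                "read_length must not exceed genome_length "
                f"({self.read_length} > {self.genome_length})"
            )


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated read set.

    ``error_rate`` is the per-base substitution probability; substituted bases
    are replaced uniformly by one of the three other bases, so ``error_rate=1``
    guarantees a mismatch at every position. ``label`` overrides the default
    labeling (0 iff error_rate == 0).
    """

    n_reads: int
    read_length: int
    error_rate: float
    seed: int
    paired: bool = False
    insert_size_mean: int = 500
    label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(
                f"error_rate must be in [0, 1], got {self.error_rate}"
            )
        if self.n_reads < 0:
            raise ValueError(f"n_reads must be >= 0, got {self.n_reads}")
        if self.read_length < 1:
            raise ValueError(
                f"read_length must be >= 1, got {self.read_length}"
            )

    @property
    def effective_label(self) -> int:
        if self.label is not None:
            return self.label
        return 0 if self.error_rate == 0.0 else 1


@dataclass(frozen=True)
class SyntheticGenome:
    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledRead:
    """A read with optional truth label and simulated provenance.

    ``label`` is 1 for erroneous reads and 0 for correct ones. For simulated
    reads ``origin_start`` is the 0-based offset of the source substring on
    the forward strand and ``origin_strand`` records whether the read was
    reverse-complemented.
    """

    read_id: str
    sequence: str
    label: int | None = None
    origin_start: int | None = None
    origin_strand: str | None = None
    quality: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def required_read_count(spec: CoverageSpec) -> int:
    """Read budget N such that C = L*N/G, rounded to the nearest integer.

    Examples
    --------
    >>> required_read_count(CoverageSpec(30, 4641652, 300))
    464165
    """
    n = spec.coverage * spec.genome_length / spec.read_length
    return max(1, int(math.floor(n + 0.5)))


def generate_genome(length: int, seed: int, identifier: str = "synthetic") -> SyntheticGenome:
    """I.i.d. uniform A/C/G/T genome; deterministic in (length, seed)."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length).tobytes().decode("ascii")
    return SyntheticGenome(identifier=identifier, sequence=seq)


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``error_rate``.

    Replacement is uniform over the three other bases: the base's index in
    BASES is shifted by 1..3 modulo 4, so a hit always changes the base.
    """
    if error_rate == 0.0:
        return reads
    hit = rng.random(reads.shape) < error_rate
    # map ASCII -> 0..3 index
    idx = np.zeros(reads.shape, dtype=np.uint8)
    for i, b in enumerate(BASES):
        idx[reads == b] = i
    shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
    idx = np.where(hit, (idx + shift) % 4, idx)
    return BASES[idx]


def simulate_labeled_reads(
    genome: SyntheticGenome,
    params: SimulationParams,
    read_id_prefix: str = "read",
) -> list[LabeledRead]:
    """Simulate reads with uniform starts, random strand and substitutions.

    Minus-strand reads are reverse-complemented after the substring is taken;
    ``origin_start`` always refers to the forward-strand coordinates of the
    source substring.
    """
    L = params.read_length
    G = len(genome)
    if L > G:
        raise ValueError(f"read_length {L} exceeds genome length {G}")
    rng = np.random.default_rng(params.seed)
    n = params.n_reads
    if n == 0:
        return []
    starts = rng.integers(0, G - L + 1, size=n)
    strands = rng.random(n) < 0.5  # True -> minus strand
    garr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    # (n, L) matrix of origin substrings
    mat = garr[starts[:, None] + np.arange(L)[None, :]]
    mat = _mutate(mat, params.error_rate, rng)
    label = params.effective_label
    qual = "I" * L
    reads: list[LabeledRead] = []
    for i in range(n):
        seq = mat[i].tobytes().decode("ascii")
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(
            LabeledRead(
                read_id=f"{read_id_prefix}_{i}",
                sequence=seq,
                label=label,
                origin_start=int(starts[i]),
                origin_strand=strand,
                quality=qual,
            )
        )
    return reads


def simulate_training_set(
    genome: SyntheticGenome,
    n_per_class: int,
    read_length: int,
    seed: int,
    error_rate_correct: float = 0.0,
    error_rate_erroneous: float = 1.0,
) -> list[LabeledRead]:
    """Balanced two-class read set: n correct (e=0) and n erroneous (e=1)."""
    correct = simulate_labeled_reads(
        genome,
        SimulationParams(
            n_reads=n_per_class,
            read_length=read_length,
            error_rate=error_rate_correct,
            seed=seed,
            label=0,
        ),
        read_id_prefix="ok",
    )
    erroneous = simulate_labeled_reads(
        genome,
        SimulationParams(
            n_reads=n_per_class,
            read_length=read_length,
            error_rate=error_rate_erroneous,
            seed=seed + 1,
            label=1,
        ),
        read_id_prefix="err",
    )
    return correct + erroneous
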