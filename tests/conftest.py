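import numpy as np
import pytest

import erroread as er


@pytest.fixture(scope="session")
def genome_1kb() -> er.SyntheticGenome:
    return er.generate_genome(1000, seed=7)


@pytest.fixture(scope="session")
def genome_50kb() -> er.SyntheticGenome:
    return er.generate_genome(50_000, seed=7)


@pytest.fixture(scope="session")
def separable_reads():
    """Balanced e=0 / e=1 read set at ~15x per-class coverage.

    The dense genome (1 kb, giving ~30x per-class coverage as in the target
    protocol) mirrors the method's operating regime: error-free reads share
    k-mers through genome overlap while fully erroneous reads do not, so the
    two classes share ~no k-mer mass.
    """
    genome = er.generate_genome(1000, seed=7)
    return er.simulate_training_set(genome, n_per_class=150, read_length=100, seed=42)


@pytest.fixture(scope="session")
def separable_Xy(separable_reads):
    vocab, X = er.fit_transform(separable_reads, k=11)
    y = np.array([r.label for r in separable_reads])
    return vocab, X, y
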