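"""Simulated classification benchmark: the end-to-end evaluation protocol.

One call runs the whole pipeline under controlled conditions: draw a uniform
random genome, simulate balanced e=0 / e=1 read classes, make a stratified
train/test split, fit the k-mer TF-IDF vocabulary on the training reads
only, train the requested classifiers and score them on the held-out reads.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from . import classify as _classify
from . import evaluate as _evaluate
from . import features as _features
from . import simulate as _simulate
from .evaluate import MetricsReport

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkResult:
    """Held-out metrics for one (k, algorithm) cell plus run metadata."""

    k: int
    algorithm: str
    report: MetricsReport
    n_train: int
    n_test: int
    vocabulary_size: int
    seconds: float


def simulated_benchmark(
    genome_length: int = 100_000,
    n_per_class: int = 10_000,
    read_length: int = 300,
    ks: tuple[int, ...] = (11,),
    algorithms: tuple[str, ...] = _classify.ALGORITHMS,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> list[BenchmarkResult]:
    """Run the simulated e=0 vs e=1 classification experiment.

    The same simulated read set and split are reused across every ``k`` and
    algorithm, so results across cells are directly comparable. Sub-seeds
    for the genome, the reads and the split are derived from ``seed``.
    """
    genome = _simulate.generate_genome(genome_length, seed=seed)
    reads = _simulate.simulate_training_set(
        genome, n_per_class=n_per_class, read_length=read_length, seed=seed + 1
    )
    y = np.array([r.label for r in reads])
    n_total = len(reads)
    n_test = int(round(test_fraction * n_total))
    n_train = n_total - n_test
    plan = _classify.make_split(
        [r.read_id for r in reads], y, n_train=n_train, n_test=n_test, seed=seed + 2
    )
    by_id = {r.read_id: i for i, r in enumerate(reads)}
    tr = [by_id[i] for i in plan.train_ids]
    te = [by_id[i] for i in plan.test_ids]
    train_reads = [reads[i] for i in tr]
    test_reads = [reads[i] for i in te]
    y_train, y_test = y[tr], y[te]

    results: list[BenchmarkResult] = []
    for k in ks:
        t0 = time.time()
        vocab = _features.build_vocabulary(train_reads, k)
        X_train = _features.tfidf_transform(train_reads, vocab)
        X_test = _features.tfidf_transform(test_reads, vocab)
        logger.info(
            "k=%d: vocabulary %d k-mers, features in %.1fs", k, len(vocab), time.time() - t0
        )
        for alg in algorithms:
            t1 = time.time()
            model = _classify.train(
                _classify.ModelConfig(alg, seed=seed), X_train, y_train, vocabulary=vocab
            )
            report = _evaluate.evaluate_predictions(
                y_test,
                _classify.predict_labels(model, X_test),
                scores=_classify.predict_scores(model, X_test),
            )
            dt = time.time() - t1
            logger.info("k=%d %s: acc=%s mcc=%s roc=%s (%.1fs)",
                        k, alg, report.accuracy, report.mcc, report.roc_auc, dt)
            results.append(
                BenchmarkResult(
                    k=k,
                    algorithm=alg,
                    report=report,
                    n_train=n_train,
                    n_test=n_test,
                    vocabulary_size=len(vocab),
                    seconds=dt,
                )
            )
    return results
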