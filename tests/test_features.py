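import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import erroread as er
from erroread.features import Vocabulary, _code_to_kmer, _kmer_to_code

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def brute_force_tfidf(sequences, k):
    """Independent nested-loop oracle for the TF-IDF matrix.

    Works directly on strings: window counts by slicing, document frequency
    by membership, natural-log IDF. Returns a dense array with columns in
    lexicographic term order.
    """
    def windows(seq):
        seq = seq.upper()
        return [
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if set(seq[i : i + k]) <= set("ACGT")
        ]

    per_read = [windows(s) for s in sequences]
    terms = sorted({w for ws in per_read for w in ws})
    n = len(sequences)
    out = np.zeros((n, len(terms)))
    for j, t in enumerate(terms):
        df = sum(1 for ws in per_read if t in ws)
        for i, ws in enumerate(per_read):
            if ws and t in ws:
                tf = ws.count(t) / len(ws)
                out[i, j] = tf * math.log(n / df)
    return terms, out


class TestExtractKmers:
    @pytest.mark.parametrize(
        "seq,k,expected_counts,expected_total",
        [
            ("ACGT", 4, {"ACGT": 1}, 1),
            ("ACAC", 2, {"AC": 2, "CA": 1}, 3),
            ("ACNGT", 2, {"AC": 1, "GT": 1}, 2),  # CN, NG windows skipped
            ("AAAA", 2, {"AA": 3}, 3),
            ("ACG", 5, {}, 0),  # k > L: empty profile, not an error
        ],
    )
    def test_examples(self, seq, k, expected_counts, expected_total):
        p = er.extract_kmers(seq, k)
        assert p.term_counts == expected_counts
        assert p.total_positions == expected_total

    def test_case_insensitive(self):
        assert er.extract_kmers("acgt", 2).term_counts == er.extract_kmers("ACGT", 2).term_counts

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            er.extract_kmers("ACGT", 0)

    @given(seq=dna, k=st.integers(1, 8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_counts_sum_to_window_count(self, seq, k):
        p = er.extract_kmers(seq, k)
        assert sum(p.term_counts.values()) == p.total_positions
        assert p.total_positions == max(0, len(seq) - k + 1)


class TestVocabulary:
    def test_document_frequency_is_presence_based(self):
        v = er.build_vocabulary(["ACAC", "ACGT"], k=2)
        assert v.corpus_size == 2
        assert v.doc_freq[v.column_of("AC")] == 2  # twice in read 0, counted once

    def test_small_corpus_example(self):
        v = er.build_vocabulary(["AA", "AC"], k=2)
        assert set(v.terms) == {"AA", "AC"}
        assert v.corpus_size == 2
        assert v.doc_freq[v.column_of("AA")] == 1
        assert v.doc_freq[v.column_of("AC")] == 1

    def test_column_order_lexicographic_and_input_order_invariant(self):
        reads = ["ACGTAC", "TTGCAA", "GGGCCC"]
        v1 = er.build_vocabulary(reads, k=3)
        v2 = er.build_vocabulary(reads[::-1], k=3)
        assert v1.terms == v2.terms
        cols = list(v1.terms)
        assert cols == sorted(cols)
        assert list(v1.terms.values()) == list(range(len(cols)))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            er.build_vocabulary([], k=3)
        with pytest.raises(ValueError):
            er.build_vocabulary(["NNNN"], k=3)

    def test_doc_freq_bounds_on_simulated_reads(self, genome_1kb):
        reads = er.simulate_labeled_reads(
            genome_1kb,
            er.SimulationParams(n_reads=100, read_length=80, error_rate=0.0, seed=1),
        )
        v = er.build_vocabulary(reads, k=11)
        assert (v.doc_freq >= 1).all() and (v.doc_freq <= 100).all()

    def test_tsv_roundtrip(self, tmp_path):
        v = er.build_vocabulary(["ACGTACGT", "TTTTGGGG"], k=3)
        path = tmp_path / "vocab.tsv"
        v.to_tsv(path)
        w = Vocabulary.from_tsv(path)
        assert w.k == v.k and w.corpus_size == v.corpus_size
        assert w.terms == v.terms
        assert (w.doc_freq == v.doc_freq).all()

    def test_code_kmer_roundtrip(self):
        for term in ["A", "ACGT", "TTTTT", "GATTACA"]:
            assert _code_to_kmer(_kmer_to_code(term, len(term)), len(term)) == term


class TestTfIdfValues:
    def test_term_frequency_examples(self):
        p = er.extract_kmers("AAAA", 2)
        assert er.term_frequency(p, "AA") == 1.0
        p = er.extract_kmers("ACAC", 2)
        assert er.term_frequency(p, "AC") == pytest.approx(2 / 3)
        assert er.term_frequency(p, "GG") == 0.0

    def test_term_frequency_undefined_without_windows(self):
        p = er.extract_kmers("AC", 5)
        with pytest.raises(ValueError):
            er.term_frequency(p, "AAAAA")

    def test_idf_closed_forms(self):
        v = Vocabulary(
            k=1,
            codes=np.array([0, 1], dtype=np.int64),
            doc_freq=np.array([5, 2], dtype=np.int64),
            corpus_size=5,
        )
        assert er.inverse_document_frequency(v, "A") == 0.0  # ubiquitous term
        v2 = Vocabulary(
            k=1,
            codes=np.array([0], dtype=np.int64),
            doc_freq=np.array([2], dtype=np.int64),
            corpus_size=4,
        )
        assert er.inverse_document_frequency(v2, "A") == pytest.approx(0.693147, abs=1e-6)
        v3 = Vocabulary(
            k=1,
            codes=np.array([0], dtype=np.int64),
            doc_freq=np.array([1], dtype=np.int64),
            corpus_size=1000,
        )
        assert er.inverse_document_frequency(v3, "A") == pytest.approx(6.907755, abs=1e-6)

    def test_unseen_term_raises_keyerror(self):
        v = er.build_vocabulary(["AAAA"], k=2)
        with pytest.raises(KeyError):
            v.idf("GG")

    def test_log10_option_rescales(self):
        v = er.build_vocabulary(["AAAA", "CCCC"], k=2, log_base="10")
        assert v.idf("AA") == pytest.approx(math.log10(2))


class TestTfIdfTransform:
    def test_hand_computed_cell(self):
        vocab = er.build_vocabulary(["ACAC", "GTGT"], k=2)
        X = er.tfidf_transform(["ACAC"], vocab)
        assert X[0, vocab.column_of("AC")] == pytest.approx((2 / 3) * math.log(2), abs=1e-6)
        assert X[0, vocab.column_of("AC")] == pytest.approx(0.462098, abs=1e-6)

    def test_ubiquitous_term_column_is_zero(self):
        vocab = er.build_vocabulary(["ACGG", "ACTT"], k=2)
        X = er.tfidf_transform(["ACGG", "ACTT"], vocab)
        col = vocab.column_of("AC")
        assert X[:, col].toarray().ravel().tolist() == [0.0, 0.0]

    def test_self_transform_finite_nonnegative(self, separable_reads):
        vocab, X = er.fit_transform(separable_reads[:40], k=7)
        assert np.isfinite(X.data).all()
        assert (X.data >= 0).all()

    def test_unseen_terms_dropped(self):
        vocab = er.build_vocabulary(["AAAA"], k=2)
        X = er.tfidf_transform(["GGGG"], vocab)
        assert X.nnz == 0

    def test_zero_window_read_gives_zero_row(self, caplog):
        vocab = er.build_vocabulary(["ACGTACGT"], k=3)
        with caplog.at_level("WARNING", logger="erroread.features"):
            X = er.tfidf_transform(["NNNNN"], vocab)
        assert X.shape[0] == 1 and X.nnz == 0
        assert any("no valid k-mer window" in m for m in caplog.messages)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(8, 30))) for _ in range(20)]
        for k in (2, 3, 5):
            terms, expected = brute_force_tfidf(seqs, k)
            vocab = er.build_vocabulary(seqs, k)
            assert list(vocab.terms) == terms
            X = er.tfidf_transform(seqs, vocab).toarray()
            assert np.abs(X - expected).max() < 1e-12

    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=5, max_size=25), min_size=2, max_size=8)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tf_sums_to_one_per_read(self, seqs):
        # TF over all terms of a read partitions its windows
        k = 3
        for seq in seqs:
            p = er.extract_kmers(seq, k)
            total = sum(
                er.term_frequency(p, t) for t in p.term_counts
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_adding_read_without_term_increases_idf(self):
        reads = ["ACGTAA", "ACGTCC"]
        v1 = er.build_vocabulary(reads, k=3)
        v2 = er.build_vocabulary(reads + ["TTTTTT"], k=3)
        assert v2.idf("ACG") > v1.idf("ACG")

    def test_distinct_denominator_dialect(self):
        vocab = er.build_vocabulary(["ACAC", "GTGT"], k=2)
        X = er.tfidf_transform(["ACAC"], vocab, distinct_denominator=True)
        # denominator 2 distinct terms instead of 3 windows
        assert X[0, vocab.column_of("AC")] == pytest.approx((2 / 2) * math.log(2))

    def test_smooth_l2_dialect_matches_reference_vectorizer(self):
        from sklearn.feature_extraction.text import TfidfVectorizer

        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(12)]
        k = 4
        vocab = er.build_vocabulary(seqs, k)
        X = er.tfidf_transform(seqs, vocab, smooth_l2=True).toarray()
        docs = [
            " ".join(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs
        ]
        ref = TfidfVectorizer(analyzer=lambda d: d.split(), lowercase=False)
        expected = ref.fit_transform(docs).toarray()
        order = np.argsort(ref.get_feature_names_out())
        np.testing.assert_allclose(X, expected[:, order], atol=1e-12)


class TestSparseContract:
    def test_k15_stays_sparse(self, genome_50kb):
        reads = er.simulate_training_set(genome_50kb, 500, 101, seed=6)
        vocab, X = er.fit_transform(reads, k=15)
        assert sp.issparse(X)
        assert X.shape == (1000, len(vocab))
        # density far below any dense 4^15 materialization
        assert X.nnz <= 1000 * 87

    def test_mtx_export_roundtrip(self, tmp_path):
        import scipy.io

        seqs = ["ACGTACGT", "TTGGCCAA"]
        vocab, X = er.fit_transform(seqs, k=3)
        er.export_mtx(X, ["r1", "r2"], vocab, tmp_path / "feat")
        back = scipy.io.mmread(tmp_path / "feat.mtx")
        np.testing.assert_allclose(back.toarray(), X.toarray())
        assert (tmp_path / "feat.rows.txt").read_text().split() == ["r1", "r2"]
        cols = (tmp_path / "feat.cols.txt").read_text().split()
        assert cols == list(vocab.terms)
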