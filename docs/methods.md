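# Methods

## Problem and model

The package casts read-error filtration as binary classification. A read is
a document; its k-mers (all sliding windows of length k, case-folded,
windows containing non-ACGT characters skipped) are terms. The feature
value of k-mer *s* in read *r* is TF·IDF with

- TF = (occurrences of *s* in *r*) / (total k-mer windows of *r*), so the
  TFs of a read sum to 1 when no window is skipped;
- IDF = ln(N / N_s), where N is the number of reads the vocabulary was
  fitted on and N_s the number of those containing *s* at least once. A
  term present in every fitted read contributes exactly 0.

No smoothing and no row normalization are applied: the formulas are used
literally. Two alternative dialects exist for cross-checking, not as
defaults: `distinct_denominator=True` divides TF by the number of distinct
terms instead of windows, and `smooth_l2=True` switches to the
smoothed-IDF (1 + ln((1+N)/(1+df))) plus L2-row-normalization convention of
common text vectorizers, verified in the tests against
`sklearn.feature_extraction.text.TfidfVectorizer`. The log base is natural;
`log_base="10"` rescales every feature by a constant, which linear and tree
models are invariant to.

The vocabulary is fixed at fit time. K-mers unseen at fit time are dropped
at transform time (IDF is undefined for N_s = 0), so a read sharing nothing
with the fitted corpus maps to an all-zero row. This is deliberate: under
the tie rule below, a vocabulary-poor read is flagged erroneous, which is
the read's most likely state. K-mers are not canonicalized by reverse
complement; both strands appear in training data, so both orientations of
every genomic k-mer enter the vocabulary on their own.

Internally k-mers are packed 2 bits/base into int64 codes (k ≤ 31), and
matrices are scipy CSR. Column order is packed-code order, which equals
lexicographic k-mer order, making the column map independent of corpus
input order. Nothing ever materializes a dense 4^k axis; k = 15 on tens of
thousands of reads runs in ordinary desktop memory.

## Why the two classes separate

Training reads are simulated from a reference at per-base substitution rate
e = 0 (label 0, "correct") or e = 1 (label 1, "erroneous"; substitution is
uniform over the three other bases, so every position is wrong). At
coverage C ≈ 30×, every error-free read shares most of its k-mers with
overlapping reads (document frequency ≈ C·(L−k+1)/L per genomic k-mer),
while an e = 1 read of length 300 contributes ~290 essentially random
k-mers from a space of 4^11 ≈ 4.2M, nearly all with document frequency 1.
Linear models and naive Bayes exploit this split directly and reach perfect
or near-perfect held-out scores; deep random-forest trees memorize it. The
contrast weakens when the term space saturates (small k: at k = 7 all
16 384 possible k-mers occur in both classes and separation becomes
statistical rather than structural) or when coverage is low (an error-free
read from a sparsely covered region shares few k-mers with the corpus and
looks erroneous — by design).

## Simulator

`simulate_labeled_reads` draws start positions uniformly over the valid
range, picks strands 50/50 (minus-strand reads are reverse-complemented;
`origin_start` stays in forward-strand, 0-based coordinates), substitutes
each base independently with probability e, and records the truth label
(0 iff e = 0 unless overridden). The error model is substitution-only — no
indels, no chimeras, no quality-dependent profile — because only the
substitution rate defines the two classes. Quality strings are a constant
'I' placeholder; quality is unused throughout. `required_read_count`
computes the Lander–Waterman budget N = C·G/L, rounded half-up (this exact
rounding reproduces the three published budgets 464 165, 862 301 and
3 651 321). Paired-end simulation produces two independent records sharing
an insert; downstream stages treat mates as independent reads, since
pairing never enters the features.

The simulator emulates uniform random genomes and uniform, strand-balanced
sampling. Real genomes have repeats and compositional bias (repeat-borne
k-mers have inflated document frequency, lowering their IDF), and real
error processes are neither uniform nor e ∈ {0, 1}; passing tests on
simulated data therefore demonstrates the pipeline's correctness and the
separability mechanism, not field performance on real libraries.

## Classifiers

Fixed defaults (overridable per run): multinomial NB α = 0.1; linear SVM
C = 1 (LinearSVC; chosen because the classes are linearly separable in this
representation and a linear kernel stays tractable at 10^6+ features);
random forest with 100 trees, min_samples_split = 2, min_samples_leaf = 1;
logistic regression C = 1, L2, lbfgs; XGBoost max_depth = 3,
n_estimators = 300, learning rate 0.1, binary logistic objective, no early
stopping. NB is multinomial because the features are nonnegative and α is a
count-smoothing parameter.

Decision rule: predicted label 1 iff score ≥ threshold, with threshold 0.5
on probabilities and 0 on the SVM decision value. Ties go to label 1 —
flagging a read as erroneous is the conservative failure mode, and it makes
all-zero feature rows (vocabulary-poor reads) come out erroneous under
probabilistic models whose two posteriors tie at the class prior.

Numerical note: lbfgs stops on a gradient-tolerance test. Because these
features are O(IDF/L) spread over millions of columns, the per-coordinate
gradients start below sklearn's default tolerance and the solver would
return a constant model; the LR builder therefore sets tol = 1e-8 and
max_iter = 5000. This is a convergence setting, not a model hyperparameter.

A known representational limit: 300 depth-3 boosted trees contain at most
~2100 split nodes. When class membership is encoded only in per-k-mer
presence across millions of columns, that budget cannot cover the
error-free class read-by-read, so XGBoost plateaus well below the other
four models on this task (≈0.91 training accuracy at the benchmark scale).
This is a property of the fixed configuration, not of the implementation;
the random forest, whose trees grow to full depth, does not share it.

Splits are stratified by label and seeded; cross-validation is stratified
k-fold (default 5). On a fixed feature matrix, fold-internal validation
mildly favors linear models: columns unique to a held-out read are unseen
by the fold's training rows, which leaves them weightless for SVM/LR
(intercept decides, correctly) but skews multinomial NB toward the class
with the smaller total feature mass. At realistic corpus sizes the effect
vanishes because erroneous reads share k-mers among themselves.

## Evaluation conventions

The positive class of every metric is the ERROR-FREE read (label 0):
TP = error-free predicted error-free, TN = erroneous predicted erroneous.
This inversion relative to the classifier's "1 = erroneous" output is
pinned in `evaluate.confusion` and unit-tested. Ratios with zero
denominators are reported as absent (`None`), never as 0. ROC-AUC negates
the native scores (which rank erroneous reads high) so that it, too, treats
error-free as positive; the value is identical to the AUC computed in the
native orientation.

Truth labels for real reads come from SAM: per read, the primary
alignment's aligned-base count (sum of CIGAR M/=/X lengths; insertions and
clips excluded; unmapped = 0) is compared to a threshold T — label 0 iff
count ≥ T. Secondary and supplementary records are ignored; a duplicate
primary record is an error. An `use_as_tag` flag substitutes the aligner's
AS tag for the CIGAR-derived count. Raising T can only move labels from
correct to erroneous (monotonicity), which the tests assert. Duplicate-read
analysis counts exact sequence duplicates (optionally also
reverse-complement matches) — an approximation of clustering-based
deduplication tools.

## Benchmark protocol and problem sizes

`erroread.simulated_benchmark` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: uniform 100 kb genome → 10 000 reads per
class → stratified 75/25 split → train-only vocabulary → train → held-out
metrics. These sizes keep a full five-model run with millions of feature
columns inside a few minutes on one CPU while preserving the regime that
makes the method work (30× per-class coverage at L = 300). At this scale
the linear/NB models reproduce their published near-perfect figures;
residual shortfalls are the k = 7 saturation effect and, at L = 101
(7.6× training coverage of the error-free class), occasional
sparsely-covered error-free reads — both discussed above. Sub-seeds for the
genome, reads and split are derived additively from the single run seed, so
one integer fixes the entire experiment byte-for-byte.

## Limitations

- Substitution-only error model; real base-caller error profiles, indels
  and adapter contamination are out of scope.
- Truth labeling of real reads depends on the aligner's primary-alignment
  choice and on T; reads shorter than T can never be labeled correct.
- The vocabulary is genome- and run-specific; a trained model does not
  transfer across organisms.
- Tree-ensemble results are configuration-bound (see the XGBoost note).
- External aligners/assemblers are consumed only through their SAM output;
  the package never invokes them.
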