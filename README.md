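# erroread

Classify next-generation sequencing reads as **erroneous (1)** or **correct
(0)** from their k-mer content alone, and filter FASTQ files accordingly —
no alignment, multiple sequence alignment or k-mer-spectrum hashing at
prediction time.

The package is aimed at people preparing Illumina-style short-read data for
assembly or mapping who want a lightweight, trainable read filter: simulate
labeled training reads from a reference, train one of five standard
classifiers on TF-IDF–weighted k-mer profiles, then split any FASTQ into a
"correct" and an "erroneous" partition.

## The model

Reads are treated as documents and their k-mers as terms. For read *r<sub>i</sub>*
and k-mer *s<sub>ij</sub>* occurring *f<sub>ij</sub>* times among the read's
sliding windows,

```
TF_ij  = f_ij / (#k-mer windows in r_i)
IDF_ij = ln(N / N_ij)
TF-IDF_ij = TF_ij · IDF_ij
```

where *N* is the number of training reads and *N<sub>ij</sub>* the number of
reads containing the k-mer at least once. A k-mer that is frequent within a
read but rare across the data set scores high; k-mers shared by every read
score zero. Error-free reads drawn from a genome share k-mers with every
overlapping read, while reads riddled with substitution errors carry k-mers
seen (almost) nowhere else — that contrast is what the classifiers learn.

Five classifiers are supported with fixed default hyperparameters:
multinomial naive Bayes (α = 0.1), linear SVM (C = 1), random forest
(100 trees), L2 logistic regression (C = 1, lbfgs) and XGBoost
(depth 3, 300 rounds, η = 0.1).

Training data come from a wgsim-style simulator: reads are drawn uniformly
from both strands of a (real or synthetic) genome and each base is
substituted with probability *e*; *e* = 0 gives the correct class, *e* = 1
the erroneous class. The read budget for coverage *C* over a genome of
length *G* follows the Lander–Waterman relation *C = LN/G*. For evaluating
on real reads, truth labels are derived from a SAM file: a read is "correct"
when its primary alignment covers at least *T* bases (sum of CIGAR M/=/X
lengths; unmapped ⇒ erroneous), with *T* ∈ {90, 80, 70, 60} by default.
Metrics (accuracy, precision, recall, F1, MCC, ROC-AUC) use the error-free
read as the positive class.

## Worked example

```sh
erroread simulate --genome-length 10000 --coverage 30 --read-length 100 \
                  --seed 7 --out-prefix sim
# simulated 3000 reads (1500 per class) -> sim.fastq

erroread train --fastq sim.fastq --k 11 --model svm --seed 7 --out-dir model
# trained svm (k=11) on 2250 reads; vocabulary 119368 k-mers; held-out accuracy 1.0000

erroread classify --bundle model --fastq sim.fastq --out-prefix filtered
# 3000 reads -> 1500 correct, 1500 erroneous

cut -f1,2 filtered.scores.tsv | tail -n +2 > predictions.tsv
erroread evaluate --predictions predictions.tsv --truth-labels sim.labels.tsv \
                  --out report.json
# labels: accuracy=1.0000
```

`simulate` derives the total read budget from the Lander–Waterman equation
(30 × 10000 / 100 = 3000 reads, split over the two classes), writes the
genome, a labeled FASTQ, a `read_id → label` TSV and a manifest. `train`
holds out 25 % of the reads, fits the k-mer vocabulary on the training part
only, runs fivefold cross-validation and reports held-out metrics; here the
linear SVM separates the two classes perfectly, as expected when every
error-free read shares 11-mers with its neighbours (30× coverage) and every
fully-erroneous read is vocabulary-poor. `classify` partitions the input
FASTQ exactly (1500 + 1500 = 3000) and `evaluate` confirms the partition
against the simulation's truth labels — all metrics 1.0, MCC 1.0.

The same steps run from Python via `erroread.simulate_training_set`,
`erroread.fit_transform`, `erroread.train` / `predict_labels` and
`erroread.evaluate_predictions`; `erroread.simulated_benchmark` wraps the
whole protocol in one call.

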