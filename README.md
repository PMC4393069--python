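# sumohunt

Prediction of protein SUMOylation sites from local sequence context.

SUMO (small ubiquitin-like modifier) attaches covalently to specific — not
all — lysine residues of its target proteins, frequently inside the
consensus motif **ΨKXE** (hydrophobic Ψ, target lysine K, any residue X,
glutamate E), but in roughly a quarter of validated sites outside it.
`sumohunt` frames site identification as binary classification of
lysine-centered peptide windows: every lysine in a protein is a candidate,
its surrounding residues are encoded numerically, and a random forest votes
on whether the site is SUMOylated.  The package is aimed at computational
biologists who want a transparent, fully reproducible reference pipeline
for this class of PTM predictor — every stage, from window extraction to the
classifier itself, is plain inspectable code.

## Method

For a window of ``w = 2·f + 1`` residues centered on a candidate lysine
(``f`` ∈ {3, 5, 10}; window 7 is the default, since prediction accuracy
peaks there), each position is encoded with 16 amino-acid property scales
(hydropathy, polarity, bulkiness, accessible surface area, isoelectric
point, ...) in AAIndex1 format, giving a feature vector of
``16·w`` = 112/176/336 real values.  Windows overhanging a protein terminus
are padded with `X`, which encodes as the per-scale mean.

The classifier is a Breiman-style random forest of ``n = 10`` trees: each
tree grows on a bootstrap sample, considers ``mtry = ⌊log₂ M⌋ + 1`` random
features per node, and splits by maximal Gini impurity decrease with
thresholds at midpoints of sorted values.  Prediction is by majority vote;
a window is called positive when the vote fraction exceeds 0.5 (an exact
tie is conservatively negative).

Evaluation follows the full classical battery — seeded percentage split,
k-fold cross-validation, the jackknife (leave-one-out), and the
self-consistency test — summarized by

    SN  = TP/(TP+FN)          SP  = TN/(TN+FP)
    AC  = (TP+TN)/total       MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with AUC computed from vote fractions by the mid-rank Mann–Whitney
statistic.  A positional frequency module tabulates residue occurrence at
every window offset (the 20 × 21 count matrix of the 293 curated modified
sites ships with the package) and tests windows against the ΨKXE rule.

## Worked example

Generate a synthetic benchmark (positives sampled from the packaged
positional count matrix, negatives with uniform flanks), then evaluate the
forest:

```console
$ sumohunt simulate --n-pos 293 --n-neg 293 --seed 7 -o bench
586 windows (seed=7) -> bench.tsv, bench.arff

$ sumohunt evaluate bench.arff --protocol self --seed 7
{
 "rounded": {
  "protocol": "self-consistency",
  "AC%": 99.32, "SN%": 98.98, "SP%": 99.66, "MCC": 0.99, "AUC": 1.0,
  "TP": 290, "FP": 1, "TN": 292, "FN": 3
 }, ...
}

$ sumohunt evaluate bench.arff --protocol kfold --k 10 --seed 7
... "AC%": 91.3, "SN%": 87.37, "SP%": 95.22, "MCC": 0.83, "AUC": 0.96 ...
```

Self-consistency (evaluating on the training instances) is the optimistic
upper bound — the forest nearly memorizes the 586 windows (AC 99.32%).
Ten-fold cross-validation gives the honest generalization estimate on this
benchmark: AC 91.3%, MCC 0.83, AUC 0.96.  The gap between the two is
expected and real.  `sumohunt build-dataset`, `train` and `predict` run the
same pipeline on real FASTA + site-annotation inputs; `sumohunt freq`
emits the positional frequency matrix and consensus-motif fraction of a
window dataset.

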