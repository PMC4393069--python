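# Methods

## Problem and model

SUMOylation modifies a subset of a protein's lysines.  `sumohunt` scores
each lysine from its local sequence context only: a peptide window of
length `2f+1` centered on the candidate lysine (flank `f` ∈ {3, 5, 10};
default 3, where prediction accuracy is best).  No structural, evolutionary
or solvent-accessibility information enters the model — local
physicochemistry stands in for the docking geometry between SUMO, the
conjugating enzyme and the substrate.

Each window position is encoded with 16 amino-acid property scales, in a
fixed order, giving `16·(2f+1)` features (112/176/336).  Raw coefficients
are used without standardization — decision trees are invariant to monotone
per-feature rescaling, so standardization could only matter through
tie-breaking; `PropertyTable.standardized()` exists for scale-sensitive
consumers.  The 16
encodings of one position are all functions of the same residue identity,
hence highly redundant; the forest tolerates this, and it means feature
ordering (position-major here: all 16 properties of position −f, then
−f+1, ...) affects interoperability but not accuracy.

### The packaged property file

The packaged AAIndex1-format file mixes published scale values
(Kyte–Doolittle hydropathy, Grantham polarity, Zimmerman bulkiness and
isoelectric point, Chothia tripeptide ASA, Hopp–Woods hydrophilicity,
residue molecular weight, Charton steric parameter) with synthetic
surrogate entries — format-correct scales with plausible ranges whose
`D` records are explicitly marked "synthetic surrogate coefficients" — for
the scales whose authentic values could not be bundled.  Nothing in the
pipeline's logic, tests, or reported quantities depends on specific
coefficient values; the surrogates exist to keep the 16-scale table
complete and the feature dimensionality contractual.  Users with access to
the AAIndex database can drop in the authentic entries; `parse_aaindex1`
reads any well-formed AAIndex1 text.

## Dataset construction

* Site annotations are 1-based; every annotated modified position must be
  a lysine in its sequence, and every *other* lysine of an annotated
  protein is assumed unmodified.  A site reported both modified and
  unmodified is modified (positives are experimentally anchored;
  negatives are absence-of-evidence).
* Windows overhanging a terminus are padded with `X` (encoded as the
  per-scale mean) rather than dropped, keeping sites near protein ends.
* Redundancy removal collapses exact-duplicate peptide strings at the
  chosen window length; label conflicts among duplicates resolve to
  positive.  Similarity-based (homology) reduction is deliberately out of
  scope.
* Class balancing keeps all positives and a seeded uniform sample of
  negatives of equal count; the seed is recorded in dataset provenance.
* Non-standard residue codes (B, Z, U, O, J) map to `X` with a warning.

## The forest

The classifier is implemented from first principles so that every
contract is testable:

* **Trees.**  Binary CART-style trees, split criterion Gini impurity
  decrease, candidate thresholds at midpoints between consecutive distinct
  sorted values of a feature, grown to purity (minimum leaf size 1,
  unlimited depth), no pruning.  A node splits only if some candidate
  improves impurity by more than 1e-12 (guards float noise).
* **Randomization.**  Each of the `n_trees` (default 10) trees grows on a
  bootstrap sample (n draws with replacement); each node considers a
  uniform random subset of `mtry` features, default `⌊log₂ M⌋ + 1`.  A
  single master seed spawns one independent stream per tree
  (`numpy.random.SeedSequence.spawn`), so trees are mutually independent
  but the whole forest is a pure function of (data, parameters, seed).
* **Deterministic tie-breaks** (part of the model contract, relied on by
  the brute-force oracle tests): among equally good splits the lowest
  feature index wins, then the smallest threshold; a leaf with tied class
  counts votes negative; a forest vote fraction of exactly 0.5 predicts
  negative.  The conservative tie direction is a deliberate choice for a
  site predictor, where a false positive costs wet-lab effort.
* **Degenerate draws.**  A bootstrap sample containing one class yields a
  bare leaf tree voting that class.
* Models serialize to versioned JSON (trees, parameters, seed) and reload
  to bit-identical predictors.

With `bootstrap=False, n_trees=1, mtry=M` the forest reduces to a single
deterministic exhaustive Gini tree; the test suite verifies this
configuration against an independently written brute-force tree builder on
small binary datasets.

## Evaluation battery

* **Percentage split**: seeded uniform shuffle, first `⌊n·p/100⌋`
  instances train, rest test.  WEKA-era split tools claimed to select the
  most favorable training instances, a behavior with no public
  specification; exact seeded reproducibility was chosen over fidelity to
  an unknown procedure.
* **k-fold CV**: seeded partition into k near-equal folds; pooled
  confusion counts are reported (with AUC over pooled out-of-fold
  scores) plus per-fold reports where defined.  Stratification is off by
  default, available by flag.
* **Jackknife** = k-fold with k = n.  **Self-consistency** trains and
  evaluates on the identical instances (optimistic upper bound).
* **Metrics**: SN/SP/AC as percentages, MCC with the zero-denominator
  case defined as 0, AUC by mid-rank Mann–Whitney (ties get half credit),
  equivalent to trapezoidal ROC integration.  Display rounding is 2
  decimals; raw values are always emitted alongside.

## Synthetic data

The packaged 20×21 positional count matrix of 293 curated modified
21-mers drives two generators:

* **Exact-marginal constructor** (deterministic): each offset column's
  residues are laid out in fixed row order repeated by count; row *i*
  across columns becomes window *i*.  Columns whose counts sum below the
  window total are completed with terminal `X` padding — the curated
  windows overhang protein ends, so edge columns are genuinely short —
  allocated outward-monotonically so every window remains a valid
  end-padded peptide.  By construction, re-tabulating positional
  frequencies recovers the source matrix in all 420 cells; this
  round-trip is the package's strongest end-to-end identity and what
  `scripts/acceptance.py` recomputes.
* **Samplers** (seeded): positives drawn position-independently from the
  matrix's per-column distributions; negatives with uniform i.i.d. flanks
  around a center lysine.  The standard benchmark is 293 + 293 windows.

Columns are modeled independently because the count matrix carries only
marginal information.  Real SUMOylation data has inter-position
dependence, protein-level context and homology structure, none of which
these fixtures emulate — passing tests demonstrate that the pipeline's
machinery is correct and that it recovers a planted positional signal, not
that any particular accuracy will transfer to real proteomes.

On this benchmark the Bayes-optimal classifier (likelihood ratio of the
generating distributions, window 7) reaches ≈ 92% accuracy by Monte-Carlo
evaluation; the default 10-tree forest attains ≈ 86–91% pooled 10-fold CV
accuracy across seeds (mean ≈ 88%) and ≈ 99% self-consistency.  An
independent implementation (scikit-learn's forest with identical
hyperparameters) lands in the same range, so this is the method's ceiling
on this generator, not an implementation artifact.

## Defaults

| Parameter | Default | Why |
|---|---|---|
| flank | 3 (window 7) | accuracy peaks at window 7 |
| n_trees | 10 | the reference configuration |
| mtry | ⌊log₂ M⌋ + 1 | classic forest default for M features |
| split | 93% train | the reference split for held-out testing |
| k | 10 | standard CV granularity |
| Ψ set | {A, F, I, L, M, P, V, W} | standard apolar side chains; configurable, since the consensus literature does not fix the membership |
| tie votes | negative | conservative for site prediction |

## Known limitations

* The 16-scale property file is partly surrogate (above); swap in
  authentic AAIndex entries for production use on real proteins.
* Duplicate removal is exact-string only; homologous-but-nonidentical
  windows inflate apparent CV performance on real data.
* No out-of-bag error, variable importance, or probability calibration —
  the vote fraction is a raw ensemble fraction, not a calibrated
  probability.
* Statistical checks on the samplers use multiplicity-aware bounds
  (≈1% of cells may exceed 3 binomial SE by chance, none 5 SE); they are
  frozen-seed and hence deterministic in CI.
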