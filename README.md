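# pairstair

Monotone staircase gene-pair classifiers for ordinal outcomes.

`pairstair` screens all pairs of genes in an expression matrix for pairs
whose joint expression is monotonically related to an ordered outcome
(e.g. short / intermediate / long survival), using exact L1-optimal
monotone "staircase" classifiers on two oriented features. It provides:

- **`pairstair.staircase`** — exact weighted-L1 fitting of monotone
  upper-set boundaries in two dimensions and multi-class staircase models
  (nested boundaries, four orientations, canonical smallest-optimal-set
  tie-breaking), plus an exhaustive enumeration oracle
  (`pairstair.oracle`) used to certify optimality in the tests.
- **`pairstair.screening`** — genome-wide pair screening by cross-validated
  MAE with a pruning rule based on the full-data MAE lower bound, greedy
  gene-disjoint selection, and deterministic TSV reports.
- **`pairstair.ensemble`** — voting ensembles of disjoint pair classifiers;
  ties resolve toward the worst outcome (label 0).
- **`pairstair.metrics`** — ordinal/agreement metrics (MAE, accuracy,
  balanced accuracy, macro-F1, Cohen's kappa, multiclass MCC) computable
  from the confusion matrix alone.
- **`pairstair.resampling`** — training bootstrap with percentile CIs,
  label-permutation tests for pair MAE, gene-set overlap randomization
  tests.
- **`pairstair.datasets`** — TSV/CSV IO, MAD gene filtering, stratified
  train/test splitting (nearest-integer, half-away-from-zero per class).
- **`pairstair.simulate`** — synthetic expression data with planted
  monotone gene pairs for end-to-end testing without downloads.

Class index 0 always denotes the **worst** clinical outcome; label files
declare the order with a `#order: worst,...,best` directive line.

## CLI

A single `--seed` makes each run reproducible; every output directory gets
a `manifest.json` with parameters and input hashes.

```sh
# synthetic data with one planted pair among noise genes
pairstair simulate --n-samples 150 --n-genes 50 --flip-rate 0.1 --seed 0 --out sim/

# screen all gene pairs (5-fold CV, at least 5 disjoint top pairs)
pairstair screen sim/expression.tsv sim/labels.tsv \
    --folds 5 --min-disjoint 5 --seed 0 --out screen/

# build a voting ensemble from the selected pairs and predict
pairstair ensemble screen/screen.tsv sim/expression.tsv sim/labels.tsv \
    --size auto --seed 0 --out ens/

# score predictions
pairstair evaluate ens/predictions.tsv sim/labels.tsv --out eval/

# uncertainty / significance
pairstair bootstrap train_e.tsv train_l.tsv test_e.tsv test_l.tsv \
    --n-boot 1000 --seed 0 --out boot/
pairstair permtest sim/expression.tsv sim/labels.tsv g00000 g00001 --n-perm 9999
```

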