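# panelminer

Graph-based feature-panel selection and association-rule mining for
multi-subtype expression cohorts.

Given a samples × features expression matrix with a subtype label per
sample — the motivating case is discriminating the three renal-cell
carcinoma subtypes (clear-cell/KIRC, papillary/KIRP, chromophobe/KICH) from
mRNA or miRNA profiles — the pipeline:

1. **preprocesses**: removes redundant (zero-variance / duplicate) features,
   makes a stratified 70/10/20 hold-out split, and normalizes with
   train-estimated z-score and min–max parameters;
2. **filters** by the AMGM dispersion score
   `R = mean(exp(x)) / exp(mean(x)) ≥ 1` (the arithmetic-to-geometric mean
   ratio of `exp(x)`, finite even with the zeros ubiquitous in expression
   data; `R = 1` iff the feature is constant), keeping the top *k* features
   in high-dimensional (mRNA-like) mode;
3. **selects a candidate panel** from the weighted feature graph
   `W_ij = β·(R_i+R_j)/2 − (1−β)·|cos(F_i,F_j)|`, SoftMax-scaled to
   `Ŵ = σ((W−W̄)/s)`, via Louvain community detection and a per-community
   maximum independent set of the thresholded adjacency `a_ij = [Ŵ_ij > γ]`
   (exact branch-and-bound for small communities, Boppana–Halldórsson
   clique removal for large ones);
4. **classifies** subtypes from the panel with a self-organizing stacked
   auto-encoder (layer-wise reconstruction pretraining, greedy
   width/depth growth gated on validation loss), reporting accuracy,
   per-class F1 and one-vs-rest AUC;
5. **mines association rules** from the panel discretized into
   low/medium/high thirds with FP-Growth (min_support 0.1, max_length 4,
   lift ≥ 1.1), keeps rules whose consequent is exactly one subtype, and
   ranks features by **repeat count** — the number of class rules whose
   antecedent mentions the feature — plus anchor-feature dependency
   networks.

A synthetic-cohort generator with planted structure (subtype-informative
feature groups, near-duplicate redundant blocks, constant features,
zero-inflated background, planted item-co-occurrence rules) makes every
stage testable end to end. See `docs/methods.md` for the model details and
known limitations.

## Worked example

```yaml
# config.yaml
mode: mirna-like
seed: 11
outdir: run
sim:
  n_features: 400
  class_sizes: [120, 64, 18]
  class_names: [KIRC, KIRP, KICH]
  n_redundant_blocks: 3
  block_size: 4
  n_constant: 8
  planted_rules:
    - features: [marker_a, marker_b]
      levels: [high, high]
      subtype: KIRC
```

```bash
panelminer run-all --config config.yaml
cat run/summary.txt
```

```text
panelminer run summary
======================

cohort: 202 samples x 400 features
classes: KICH=18, KIRC=120, KIRP=64

redundancy removal: 8 features removed, 392 retained
split: train=141, validation=20, test=41

graph: 392 nodes, 77028 weighted pairs (beta=0.6, gamma=0.3, k=None)
louvain: 2 communities, modularity=0.0042
candidate panel: 114 features

classifier: sodae (architecture [16])
  train: accuracy=100.0%  F1 [KICH:1.00, KIRC:1.00, KIRP:1.00]
  validation: accuracy=95.0%  F1 [KICH:0.67, KIRC:1.00, KIRP:0.92]
  test: accuracy=95.1%  F1 [KICH:1.00, KIRC:0.96, KIRP:0.92]

rule mining: 154574 class-consequent rules (min_support=0.1, max_length=4, min_lift=1.1)
  KICH: 0 class rules; top repeat counts: none
  KIRC: 90724 class rules; top repeat counts: marker_b(13564), marker_a(13256), ...
  KIRP: 63850 class rules; top repeat counts: inf_g0_0006(5358), inf_g0_0024(5345), ...
```

Reading the output: the 400-feature graph carries 392·393/2 = 77,028
weighted pairs; the panel feeds a self-organizing auto-encoder that reaches
95.1% test accuracy; the two planted markers top the KIRC repeat-count
table by a wide margin; and KICH — at 18/202 ≈ 8.9% prevalence, below the
0.1 minimum support — yields exactly zero class rules, reproducing the
rare-subtype suppression characteristic of strongly imbalanced cohorts.

The same stages are available as library calls
(`generate_cohort`, `split_holdout`, `amgm_scores`, `build_weight_matrix`,
`louvain_partition`, `select_candidates`, `fit_classifier`, `evaluate`,
`discretize`, `mine_frequent`, `class_association_rules`, `repeat_counts`,
`dependency_network`) and as CLI subcommands
(`simulate`, `preprocess`, `select`, `classify`, `mine`, `run-all`,
`report`).

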