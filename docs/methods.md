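# Methods

## Overview

`panelminer` implements a five-stage discovery pipeline for multi-subtype
expression cohorts: (1) reading and preprocessing, (2) AMGM dispersion
filtering, (3) graph-based feature selection (weighted feature graph →
Louvain communities → per-community maximum independent sets), (4) subtype
classification with a self-organizing auto-encoder, and (5) FP-Growth
association-rule mining of the discretized candidate panel with
repeat-count ranking. The package ships a synthetic cohort generator so
every stage is testable without any external download.

## Preprocessing

Tables are read samples × features (a features-in-rows orientation flag
transposes). Redundant features are removed as the minimal defensible
reading of that step: zero-variance columns and exact duplicate columns
(first kept by feature-ID order). This also protects the two downstream
pathologies — σ = 0 under z-scoring and an undefined cosine for
zero-norm vectors.

The hold-out split is 70/10/20 train/validation/test, stratified per class
with largest-remainder rounding (deterministic tie-break by partition
order). Stratification matters because the smallest subtype has ~9% of the
samples; an unstratified 10% validation slice could miss it entirely.

Two per-feature transforms, both with parameters estimated on training data
only: z-score `y = (x − μ)/σ` (population σ) and min–max
`y = (x − Min)/(Max − Min)`. At inference, min–max outputs are clipped to
[0, 1] because discretization downstream requires that range.

## AMGM dispersion score

The AMGM ratio of a feature vector is `R = AM/GM ≥ 1`, equal to 1 exactly
for constant features. Because a single zero makes the geometric mean
vanish — and zeros are ubiquitous in expression data — the default variant
exponentiates first:

    R = mean(exp(x)) / exp(mean(x))

computed as `mean(exp(x − x̄))`, which is overflow-immune. Scores are
computed on min–max-scaled *training* data: the exponential is unbounded on
raw intensities, and train-only scoring keeps the test partition untouched
by selection. Constant columns are forced to exactly 1.0 (the mathematical
value; the floating-point mean of n equal numbers need not be one of them).

In mRNA-like mode the top k = 1000 features by R (ties by feature ID) feed
the graph stage; miRNA-like mode skips the filter.

## Feature graph, communities, node selection

For features i ≠ j:

    W_ij = β · (R_i + R_j)/2 − (1 − β) · |cos(F_i, F_j)| ,   W_ii = 1

with β = 0.6 (miRNA-like) or 0.5 (mRNA-like). Weights are rescaled by the
logistic ("SoftMax") map `Ŵ = σ((W − W̄)/s)` where W̄, s are the mean and
population SD of the off-diagonal upper-triangle weights (the constant
diagonal would bias them). Louvain modularity maximization runs on the
complete graph with Ŵ edge weights and self-loops dropped; node visiting is
seeded, so partitions are reproducible. The Boolean adjacency is
`a_ij = 1 ⟺ Ŵ_ij > γ` (strict) with zero diagonal, γ = 0.3 by default.
Within each community a maximum independent set of that adjacency is
selected: exact branch-and-bound (lexicographically smallest optimum, so
ties break toward the lowest feature ID) for communities of ≤ 25 nodes, the
Boppana–Halldórsson clique-removal approximation above that, implemented on
bitmask adjacency for determinism and scale. The candidate panel is the
union of the per-community sets.

A property worth stating plainly: because higher W means *more relevant and
less redundant*, thresholding Ŵ from above makes exactly those pairs
adjacent, and the per-community MIS therefore consists of pairwise
*low-weight* (mutually redundant or jointly low-relevance) features. With
γ = 0.3 (below the sigmoid midpoint) roughly 80% of pairs are adjacent, so
each community contributes only a small independent set and the panel size
tracks the community count. Panel diversity is consequently a function of
how many communities Louvain finds, not of an explicit redundancy-removal
objective. On clean synthetic cohorts the weight matrix is close to uniform
and Louvain returns very few communities (2–5), so the panel concentrates
on one or two coherent feature families; this is the main divergence
between what the selection stage achieves on synthetic data and on real,
heterogeneous expression data, and it is measured — not hidden — by the
acceptance checks (see Limitations).

## Classification

The reference classifier ("sodae") is a stacked auto-encoder that sizes
itself: starting from one sigmoid encoding layer it first doubles the layer
width, then appends layers of half width, accepting a growth step only
while the relative validation-loss improvement exceeds a tolerance (default
0.01, max 3 layers / 64 units). Each layer is pretrained to reconstruct its
input (linear decoder, MSE), then the stack plus a softmax head is
fine-tuned end-to-end with full-batch Adam (default 150/300 epochs,
lr 0.01). The final model is the candidate with the best validation
accuracy. Everything is plain numpy seeded from one integer, so training is
bit-reproducible. Two further kinds share the fit/predict/score contract: a
fixed sklearn MLP baseline and a nearest-centroid oracle used as an
independent cross-check in tests.

Evaluation: headline accuracy is 100·correct/total (identical to the pooled
one-vs-rest micro average of precision/recall). Per class, one-vs-rest
TP/TN/FP/FN give precision, recall, F1 and a per-class accuracy; AUC is
one-vs-rest from the continuous class score. A class absent from a
partition reports AUC as undefined (None), never 0.

## Rule mining

Min–max-scaled panel values are discretized into equal-width thirds
(low/medium/high, left-closed upper bins; edges configurable), each sample
becomes a transaction of (feature, level) items plus one class item, and
frequent itemsets are mined by FP-Growth (items ordered by descending
support, ties by name — any valid ordering yields the same itemset family,
which the tests assert against a brute-force Apriori oracle). Defaults:
min_support 0.1, max_length 4, min_lift 1.1. Rule metrics are
support(A→C) = P(A∪C), confidence = P(A∪C)/P(A), lift = P(A∪C)/(P(A)P(C)).

Supports are computed on the full discretized cohort (all partitions
pooled) with train-fitted scaling parameters. A subtype whose prevalence is
below min_support can never appear in a frequent itemset, so its class-rule
list is exactly empty — the suppression the default imbalanced cohort
reproduces for its smallest subtype.

The pipeline's mine stage generates class-consequent rules directly by
FP-Growth conditioned on the class item (only that subtype's transactions
feed the tree, supports stay cohort-relative, antecedent supports are
counted on the boolean item matrix). This is provably the same rule set as
"mine everything, generate all rules, keep exact-class consequents" — the
equivalence is asserted on random databases in the tests — but it avoids
expanding the full frequent-itemset lattice, which for a correlated
~70-feature panel at these thresholds holds on the order of 10⁶ itemsets.

A feature's repeat count is the number of class rules whose antecedent
mentions it at any level (levels aggregate per molecule). Dependency
networks count, for an anchor feature, how often each partner co-occurs in
the antecedents of the anchor's class rules, with optional support/lift
cuts exposed as free parameters. Note that partner ranking reflects the
number of rule *extensions* a pair admits; items that are near-constant at
one level co-occur in the most rules, so the top edge is not necessarily
the statistically strongest partner.

## Synthetic cohorts

The generator emulates a TCGA-style renal-carcinoma cohort: three strongly
imbalanced subtype classes (default 611/321/89, scalable), log-normal
intensities, and five feature archetypes:

- **informative** — log-mean shifted by `effect_size` (default 3, log
  scale) in one subtype, up or down, for a random `responder_frac`
  (default 0.8) of that subtype's samples; features are assigned
  round-robin to `n_informative_groups` signal patterns (default 6: up and
  down per class) and share a per-group latent factor (loading 0.4), so
  within-group correlation is moderate rather than duplicate-level —
  real expression signatures are heterogeneous;
- **redundant** — blocks of near-duplicate copies of an informative
  template (multiplicative jitter, within-block cosine > 0.95), exercising
  the redundancy contracts;
- **constant** — identically zero;
- **noise** — zero-inflated: each feature is detected in a uniform(0.05,
  0.95) fraction of samples and sits at a low detection floor
  (exp N(−4, 0.5)) elsewhere. Dropout zeros are the very reason the
  modified AMGM exists; a dense homogeneous background would be
  unrealistic and would make the dispersion filter trivial;
- **planted-rule** — features named by planted (features, levels, subtype)
  triples: a uniform [0, 1] background, with samples of the target subtype
  forced into the named level's band with probability 0.95.

One integer seed fully determines the cohort; no global RNG state is
touched. What the generator does *not* emulate: batch effects, library-size
confounding, count noise, clinical covariates, and — most consequentially —
the messy hierarchical correlation structure of real transcriptomes that
gives the graph stage its many communities (see Limitations).

## Pipeline and reproducibility

One master seed derives a stable per-stage seed as the first four bytes of
SHA-256(`"{seed}:{stage}"`). Every artifact is TSV/JSON under the run
directory; the manifest records a config snapshot and each artifact's
SHA-256, and re-running an identical config reproduces identical checksums.
The summary report is a pure function of the manifest, so regeneration is
byte-identical. Full edge lists are materialized only for graphs of ≤ 200
nodes; per-subtype rule exports are capped at the 2000 strongest-support
rules (repeat-count tables are always complete).

Problem sizes used by the shipped end-to-end checks: a 2000-feature,
300-sample cohort (class sizes 180/94/26, mirroring the reference cohort's
imbalance at 1/3.4 scale) in mRNA-like mode (k = 1000), a 1881-feature
cohort for the edge-count identity, 200 random transaction databases for
the FP-Growth oracle comparison, and 500 random graphs for the MIS solvers.

## Limitations

- On synthetic cohorts the graph stage finds few communities (the blended
  weight matrix is near-uniform once sigmoid-scaled), so candidate panels
  concentrate on a small number of feature families and typically represent
  only a minority of the planted signal groups; downstream classification
  then plateaus near the accuracy attainable from those groups alone. The
  end-to-end recovery check asserts the intended ≥90% group representation
  and ≥95% accuracy and is expected to fail at those bounds on this
  generator, reporting the measured values.
- The exact architecture-growth rule of the original self-organizing
  auto-encoder is re-specified here as a documented greedy heuristic behind
  a pluggable interface; it is not a reimplementation of an external
  reference.
- Rule-count magnitudes depend strongly on item marginals after
  discretization and are not comparable across datasets.
- The classic AMGM variant refuses inputs containing zeros rather than
  returning an uninformative value.
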