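# Methods

## Problem and labeling model

The package treats protein thermophilicity as a binary classification
problem defined through the source organism's optimal growth temperature
(OGT): label 1 when OGT ≥ 60 °C, label 0 when OGT ≤ 30 °C; proteins from
organisms in the 30–60 °C band are outside the problem definition. The
label is a property of the *species*, not of the individual protein, which
has two consequences that shape the whole design: (i) every protein of a
species shares one label, so a model that merely recognizes species
fingerprints scores well under random splits without learning anything
about thermostability (species circularity); and (ii) honest generalization
estimates require species-disjoint test partitions and, more stringently,
test proteins with low sequence identity to anything in training.

## Data preparation

**Alphabet validation** keeps only sequences over the 20 proteinogenic
amino acids (filtering, not erroring, with a logged count; case-folded to
uppercase first). Records annotated as predicted/inferred by homology
cannot be recognized from sequence alone; an optional `evidence` metadata
column is honored when present, otherwise that filter is a no-op.

**Length filter.** Sequences shorter than the 5th or longer than the 95th
length percentile are dropped. Percentiles are nearest-rank order
statistics (the ⌈p·n⌉-th sorted value), which is unambiguous for integer
lengths: for lengths 1…100 the bounds are exactly 5 and 95.

**Redundancy reduction.** Highly similar sequences are removed by a
transparent O(n²) greedy incremental clustering: records are visited
length-descending (ties by id); a record joins the first cluster whose
*seed* has global-alignment identity ≥ 0.40, else it opens a new cluster;
seeds are the representatives. The identity kernel is a Needleman–Wunsch
global alignment (match +1, mismatch 0, linear gap −1) with identity =
matched columns / alignment columns, computed via Biopython's
PairwiseAligner. Heuristic word filters used by production clustering
tools are a performance device, not part of this contract; by construction
no two representatives reach the threshold, and the test suite verifies
this exhaustively on ~200-record fixtures. The same kernel backs the
relatedness filter (test records kept only when their maximum identity to
every training sequence is strictly below 0.50), which is an approximation
of a BLAST-identity screen and is documented as such.

**Split designs.** Two designs are produced as explicit, serializable
plans (TSV of id/level/partition):

* *nested_cv*: class-stratified 3 outer folds; each outer training set is
  re-split into class-stratified 5 inner folds. Outer folds estimate
  generalization; inner folds drive model selection only.
* *species_holdout*: all proteins of a designated species set form `test1`;
  the remainder is split into stratified inner folds. Species disjointness
  between `test1` and the CV partitions is asserted on every generated
  plan. `test2` is the relatedness-filtered subset of `test1`.

Stratification delegates to scikit-learn's StratifiedKFold (per-fold class
counts within one of ideal); all shuffling flows from the single integer
seed stored in the plan.

## Descriptors (599 features)

Block layout: basic (9) ‖ AAC (20) ‖ DPC (400) ‖ CTD-C (21) ‖ CTD-T (21)
‖ CTD-D (105) ‖ PseAAC (23), with stable feature names.

* *Basic*: mean residue mass; fraction positive {K,R,H}, fraction negative
  {D,E}, net charge per residue; fraction polar / nonpolar (polar =
  C,D,E,H,K,N,Q,R,S,T,Y); fraction aromatic {F,W,Y}; mean Kyte–Doolittle
  hydropathy; mean van der Waals residue volume.
* *CTD*: the seven classical attributes (hydrophobicity, normalized vdW
  volume, polarity, polarizability, charge, secondary-structure
  propensity, solvent accessibility), each partitioning the alphabet into
  three classes — forced by the block sizes 21 = 7×3 and 105 = 7×15.
  Composition is the class fraction; transition is (N(rs)+N(sr))/(l−1)
  over the three unordered class pairs; distribution records the sequence
  position (as % of l) of the first, 25 %, 50 %, 75 % and last occurrence
  of each class (⌈q·n⌉-th occurrence; an absent class contributes five
  zeros).
* *PseAAC*: Chou-type with λ = 3 (forced by 23 = 20 + λ) and weight
  w = 0.05 (the literature default). Sequence-order factors
  θⱼ = (1/(l−j)) Σᵢ Θ(aᵢ, aᵢ₊ⱼ) with Θ the mean squared difference of
  three residue properties (hydrophobicity, Hopp–Woods hydrophilicity,
  side-chain mass), each standardized to zero mean / unit variance over
  the alphabet. Components: fᵤ/(Σf + wΣθ) for u ≤ 20 and wθⱼ/(Σf + wΣθ)
  above; the vector sums to one.

All property scales are versioned constant tables in `_tables.py`; the
tables, not any external source, are the contract — every block is checked
against an independently coded brute-force oracle to 1e-12 on 100 random
sequences.

The hybrid recurrent models consume a per-residue 6-channel encoding
(weight, formal charge at pH 7 with H = +0.1, Grantham polarity, binary
aromaticity, Kyte–Doolittle hydropathy, vdW volume), min–max normalized
over the alphabet. Embedding-based models consume ordinal codes A→1 … Y→20.

## Embedding providers and pooling

Providers share one interface (sequence → l×d matrix). The *mock* provider
is a seeded hash-to-Gaussian map, row j = e(aⱼ) + 0.25·p(j) with seeded
residue and positional tables; it is deterministic, injects no label
information, and keeps end-to-end tests honest (any label signal must come
from the sequences). The *precomputed* provider serves a disk cache (flat
float32 binary + JSON sidecar keyed by sequence hash). The *pretrained*
adapter wraps a frozen 1024-wide protein language-model encoder,
inference-only, pooling residue positions only (special tokens stripped);
it raises an explicit error when its optional dependencies are absent
rather than falling back silently. Pooling is the arithmetic mean over the
length; it is linear and tested as such.

## Models and training

Feature-based families delegate to scikit-learn (logistic regression with
elastic-net penalty via saga; SVC with linear/RBF/polynomial kernels and
probability outputs; random forest) and XGBoost; their contract here is
hyperparameter validation, seeding and the shared probability interface.

The neural families run on a small reverse-mode autodiff core written on
numpy (float64): dense layers, batch/layer normalization, dropout,
embeddings, an unrolled LSTM, and multi-head self-attention, all verified
against central finite differences. The shared classification head — FC
d→d/2 + ReLU + batch normalization, dropout, FC to two logits — is one
component reused by the pooled-embedding, mean-pooled-embedding, recurrent
and transformer families (hidden width 512 when d = 1024). Architectural
notes:

* Bidirectional stacks run a second LSTM over per-row reversed sequences;
  the "last" state of each direction therefore always sits at a valid
  (non-padded) position, and batch padding provably never changes a
  record's prediction (tested).
* The pooled-embedding classifier applies dropout to the residue rows
  before pooling and again before the output layer, training mode only;
  the provider is frozen, so no gradient reaches it.
* The full-attention transformer optionally average-pools the embedded
  sequence with a stride before its pre-layer-norm blocks (LN → attention
  → residual, LN → feedforward → residual); the sparse variant instead
  keeps full length and masks attention to a sliding window plus g global
  tokens. The sparse mask is realized as an additive score mask — adequate
  at the problem sizes used here — rather than a block-sparse kernel.
* Whether the mean-pooled embedding model pools before or after its
  optional first FC layer was open; pooling-first is implemented.

Training minimizes the cross-entropy loss with Adam (β₁ = 0.9,
β₂ = 0.999); the learning rate is the tuned quantity, multiplied by 0.1
after 5 epochs without validation-loss improvement (floor 1e-6); early
stopping after 10 stagnant epochs (patience 0 disables it); at most 200
epochs; the best-validation-loss parameters (including batch-norm running
statistics) are restored at the end. Batch-norm uses running statistics at
inference, so single-record prediction is well defined. Everything is
deterministic under a fixed seed, including dropout masks and shuffling.

The decision threshold is 0.5 on the positive-class softmax probability,
with the boundary mapped to the positive class.

## Hyperparameter optimization

Suggestion is seeded random search over declared spaces (log-uniform,
uniform, integer, categorical); every suggested point is validated against
the space, and repeated configurations reuse the cached result. A trial
trains on the inner folds sequentially, reporting the per-fold validation
MCC; the objective is the mean over folds, ties broken by earliest trial.
Pruning: at fold step s, a trial is stopped when at least 5 prior trials
reported at that step and its value is strictly below their 80th
percentile. The percentile uses the ceiling convention (numpy
`method='higher'`): for prior values {0.5, 0.6, 0.7, 0.8, 0.9} the cutoff
is 0.9, and a candidate equal to the cutoff continues. Percentiles are
taken over all prior reports at the step, pruned trials included. The
winning configuration is retrained on the union of all inner-fold data and
evaluated only on the held-out partition; id-set leakage checks abort the
run otherwise.

## Evaluation

Seven confusion-matrix metrics as listed in the README; any metric with a
zero denominator is reported as 0 and flagged degenerate rather than
raised. BACC ≡ (recall + specificity)/2 holds exactly by construction and
is asserted property-style. ROC curves group tied scores into a single
threshold and AUC is the trapezoid rule (scikit-learn's sweep underneath).

Length-binned analysis uses equal-width bins over the observed range with
right-closed bins (a length on an internal edge joins the lower bin), so a
span of 82–712 residues with five bins gives edges 82, 208, 334, 460, 586,
712. Five bins is the default. OGT-binned analysis counts species,
proteins, tp and fn per left-closed temperature interval, the last open
above; records without OGT are excluded with a logged count.

## Synthetic data generator

Each species draws an OGT uniformly from its class range ([60, 95] °C or
[20, 30] °C — labels follow the OGT thresholds by construction), and a
residue distribution: uniform logits plus species-level Gaussian noise
(σ = 0.3), with thermophilic species shifted by 0.5·effect_size logits on
a designated subset (default D, E, K, R — a fixture choice that every model
family can detect, not a biological claim). Protein lengths are uniform on
[82, 712]. Defaults produce a few hundred proteins from 50 species.

What the generator does *not* emulate: real phylogenetic correlation
between species, motif- or structure-level signal, length–label coupling,
and database noise. Passing tests therefore demonstrate that the pipeline
is correct and that models can recover a composition-level signal under
species-disjoint evaluation — not that any model attains its published
real-data performance.

The learning-sanity checks use a species-disjoint validation split
deliberately: with a random split, the species-level composition noise
makes labels partially predictable from species fingerprints even at zero
effect size — precisely the circularity the species-holdout design exists
to exclude.

## Problem sizes and numerical choices

The test suite and examples run at desk scale by choice: learning-sanity
datasets of ≈500 proteins from 50 species with lengths 82–160 (the
composition signal is length-independent, so shorter sequences test the
same property); split-hygiene fixtures of 200 records; 100-sequence oracle
sweeps for the descriptor engine. Autodiff runs in float64; softmax is
max-shifted; probabilities are clipped at 1e-12 inside logs; batch-norm
ε = 1e-5; Adam ε = 1e-8. Greedy clustering breaks ties length-descending
then lexicographically by id, making representative choice deterministic.

## Known limitations

* The identity kernel is exact but O(l²) per pair and O(n²) per dataset;
  at genuinely large scale one would swap in a word-filtered clustering
  tool behind the same interface.
* The pretrained-embedding provider is an adapter; this repository ships
  no language-model weights, and the published headline numbers of
  embedding-based predictors on real benchmarks are not reproduced here —
  the evaluation arithmetic that summarizes them is (see
  `scripts/acceptance.py`).
* The sparse-attention variant shares the sliding-window + global-token
  *contract* with block-sparse implementations but not their memory
  profile.
* Hyperparameter search spaces are this package's own, chosen to bracket
  the architectural choices named above; random search replaces Bayesian
  suggestion, with identical bookkeeping, pruning and tie-breaking.
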