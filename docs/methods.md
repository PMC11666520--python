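# Methods

This note documents the models and procedures implemented in `dmoit`, the
choices made where the design was genuinely open, and what the synthetic
data used by the tests does and does not establish.

## Problem setting

The package classifies samples (e.g., tumors into long-term vs
non-long-term survivors, or by estrogen-receptor status) from several
omics layers measured on the same individuals: a non-negative continuous
abundance layer (mRNA expression), a [0,1]-bounded layer (DNA-methylation
beta values, "MET"), and a ternary copy-number layer ("CNV", coded −1/0/+1
for loss/neutral/gain). Three obstacles motivate the design: missing
values in the continuous layers, large numbers of noisy or redundant
features, and the split between *intra*-omics interactions (within one
layer) and *inter*-omics interactions (across layers).

## Pipeline

Default stage order: drop fully missing features → min-max scale the
continuous layers → (optional) bootstrap-stability feature selection →
adversarial imputation → attention-based classification. Copy-number data
are ternary-coded by sign and are never imputed (they arrive complete).

### Preprocessing

* **Missing-rate filter.** Only features whose missing fraction exceeds
  the threshold (default: effectively 100%) are removed; informative but
  partially observed features are retained for the imputer.
* **Min-max scaling** maps each feature's observed training-partition
  values to [0,1]. Constant features map to 0 rather than NaN; held-out
  values outside the training range are clipped. Scaling is fit on the
  training fold by default (fold-safe); a global option reproduces the
  scale-then-split ordering some studies use, which leaks a small amount
  of information from test to train.
* **Survival dichotomization.** The threshold is the nearest integer to
  the median survival time (ties round half to even, a fixed testable
  convention); samples with time strictly greater are labeled long-term
  survivors (1). All-equal times therefore produce an all-0 labeling.
* **Heterogeneity diagnostics.** Per feature: mean, coefficient of
  variation (sample SD over |mean|; 0 for constant features), and Shannon
  entropy in bits on a 20-bin histogram of the feature's own range. These
  statistics quantify how much the layers differ in scale and shape —
  the reason the shared encoder alone struggles with concatenated input.

### Bootstrap-stability feature selection (RFS)

A single variance filter is fragile: one aberrant sample can promote a
noisy feature. The selector draws B bootstrap resamples of the samples
(default B = 10), takes the k highest-variance features within each
resample (unbiased variance over observed cells only — missing values
never count as zeros), and keeps the m features most frequently selected.
Ordering is fully deterministic: selection count (desc), then mean
variance rank across resamples (asc), then feature ID. k and m default to
min(2000, p) and min(1000, k) and are exposed everywhere; the procedure
runs per layer. Equivalence with an exhaustive recomputation is tested on
small instances.

### Adversarial imputation

The imputer is a generative adversarial pair operating on one min-max
scaled continuous layer. The generator receives the matrix with missing
cells filled by Uniform(0, 0.01) noise plus the observedness mask and
proposes a complete matrix; the proposal is composited with the data
(observed cells kept verbatim). The discriminator receives the composite
plus a *hint* matrix that reveals a fraction `hint_rate` (default 0.9) of
the true mask (0.5 elsewhere) and predicts per-cell observedness. Losses:

* discriminator: per-cell binary cross-entropy against the true mask;
* generator: adversarial term (fool the discriminator on missing cells)
  plus `alpha` × mean squared reconstruction error on observed cells.

Both nets are two-hidden-layer fully connected (width = feature count),
trained with Adam (lr 1e-3) on mini-batches of 128 for 2000 iterations.
`alpha` defaults to 100 — the value the original adversarial-imputation
implementation ships with. Two empirical facts drove the remaining
defaults: with a much smaller `alpha` the generator's missing-cell
proposals drift away from the data manifold and imputation ends up worse
than a column mean; and training far beyond ~2000 iterations at these
problem sizes lets the adversarial game degrade imputation again, so the
iteration default stays at 2000 rather than the reference 10000.

Final imputation is `mask ⊙ original + (1 − mask) ⊙ generated`: observed
cells are bit-identical by construction and the output has no missing
cells. Zero, column-mean, column-median and KNN (k = 5, nan-aware
Euclidean distance) imputers are provided for benchmarking, all under the
same observed-cell-preservation contract. A fully missing column is
filled with 0 and flagged with a warning.

One structural limit worth knowing: under per-cell MCAR at rate r, a
fraction ≈ r of hidden cells in a two-feature layer lose their only
correlated partner; no imputer can beat the column mean on those cells,
which bounds how far below the mean-imputer RMSE any method can go. Tests
of correlation learning therefore score the recoverable cells.

### Attention encoders and the four architectures

Each omics layer arrives as a flat vector per sample. A linear layer maps
it to `n_tokens` × `d_model` values reshaped into `n_tokens` tokens
(default 4) with learned position embeddings — the token axis is a
design choice, since a flat feature vector has no natural sequence
structure; making it configurable keeps the attention non-degenerate
without committing to features-as-tokens (quadratic in p). Tokens pass
through `num_blocks` pre-norm transformer blocks (multi-head scaled-dot
attention with h heads of width d_model/h, concatenated and projected;
residuals; layer norm; a feed-forward of width 4·d_model) and are
mean-pooled to one vector.

The four integration designs:

* **m1** — one encoder per layer, pooled outputs concatenated into the
  MLP head: intra-omics only.
* **m2** — one shared encoder on the feature-wise concatenation:
  inter-omics, but heterogeneity makes per-layer attention hard.
* **m3** — per-layer encoders, token sequences concatenated, a second
  encoder on the combined sequence, pool, head.
* **dmoit** — the dual design: m1's per-layer paths *and* m2's shared
  path run in parallel; all pooled outputs feed one MLP head (one hidden
  layer of width d_model, dropout, 2 logits).

Encoders within one model share hyperparameters, not weights. "Combined"
always means concatenation (path widths differ). The whole stack runs on
an in-repo reverse-mode autodiff core over numpy (float64), verified
against finite differences and a brute-force per-head attention oracle.

### Training and evaluation

Cross-entropy on two logits, Adam, a fixed 50 epochs (no early stopping),
stratified 5-fold cross-validation, metrics = accuracy and class-support-
weighted F1 (a class absent from both truth and predictions contributes
F1 = 0). Hyperparameters come from a full-factorial grid (learn rate
{0.001, 0.01}; batch {32, 64, 128}; heads {2, 4, 8}; blocks {1, 2, 3};
dropout {0.01, 0.1}; d_model {32, 64, 128}) scored on an inner stratified
80/20 split of each training fold — fold-safe; a `global_grid` switch
performs one pre-CV search instead. Combinations with d_model not
divisible by the head count are skipped and logged. Ties break by inner
weighted F1, then accuracy, then grid order.

Three training defaults matter in the p ≫ n regime these models face
(hundreds of samples, thousands of features, most of them noise), where
unregularized training memorizes the training fold outright:

* **input dropout 0.3** on the flat feature vector before embedding — a
  denoising-style corruption that stops the embedding from keying on
  individual noise features;
* **decoupled weight decay 10** (with lr 1e-3, a 1% multiplicative
  shrink per step) on weight matrices only;
* **Polyak averaging of the final half of the epochs**, which removes
  the lottery of whichever weights the fixed-length schedule happens to
  end on.

All three are exposed on `EncoderConfig`/`TrainConfig`. Baseline
classifiers (logistic regression, random forest, SVM, XGBoost) run on the
feature-wise concatenation under the identical CV protocol at library
defaults with pinned seeds (logistic regression gets a raised iteration
cap so it converges).

### Interpretation

* **Permutation importance** keeps the fold-trained models fixed and
  shuffles one feature column at a time across each held-out fold
  (`n_repeats` independent permutations, seeded per feature × fold ×
  repeat), recording the weighted-F1 drop vs the unpermuted baseline,
  averaged over folds and repeats. Retraining per permuted feature would
  be both prohibitively expensive and contrary to the idea of scoring a
  fixed fitted model. Per-layer top-k selection of biomarkers follows.
* **Joint-effects sign flips.** For biomarker sets A, B, C from the three
  layers and each choice of X1's layer, every ordered triple (X1, X2, X3)
  is scored by fitting OLS `Y ~ X1` and `Y ~ X1 + X2 + X3` (linear
  probability models on the 0/1 label — sign comparison only, so the
  linear fit is appropriate and scale-invariant; no standardization) and
  recording whether X1's coefficient changes sign — the omitted-variable
  signature of a cross-layer joint effect. Coefficients within 1e−12 of
  zero count as sign 0 and never flip. Perfectly collinear triples
  (design rank < 4) are excluded from flip counts and reported
  separately. Triples per X1-layer equal |A|·|B|·|C| rearranged; sets of
  sizes 10/14/4 give 560 per layer choice.

## Synthetic data

The generator emulates the three-layer structure on shared samples:
labels first (Bernoulli π); latent standard-normal features; informative
columns shifted by `beta_intra` within-class SDs between classes (a
Gaussian class-conditional model, hence an exactly logistic posterior
with per-feature coefficient `beta_intra`); fixed cross-layer pairs of
informative features receive a shared component whose sign flips with the
class, so the pair's correlation is ±ρ by class and only the cross-layer
*product* is predictive — signal a per-layer encoder cannot represent
but a shared encoder can. Observed values are monotone marginal
transforms of a noisy copy of the latents (log-normal for abundance;
Gaussian-copula Beta for methylation; per-feature symmetric thresholds
for ternary copy number), so the signal survives but is attenuated.
Missingness is MCAR at `missing_rate` in the two continuous layers only.

Default scenario: n = 400, features (500, 400, 200), informative
(20, 15, 10), `beta_intra` 0.8, `beta_inter` 1.0, π 0.5, missing rate
0.15, observation noise SD 0.5. Survival times are log-normal with a
risk score proportional to the same discriminant; zero effect sizes make
them independent of the features.

What the synthetic data does **not** emulate: real marginal distributions
of sequencing data, batch effects, informative (MNAR) missingness,
feature-feature correlation beyond the planted pairs, and annotation
structure. Passing tests therefore demonstrate that the machinery —
imputation, selection, encoders, importance, joint effects — behaves as
specified under controlled signal, not that any particular biological
dataset will reach a particular accuracy.

## Numerical and reproducibility notes

* All randomness flows through numpy Generators seeded explicitly; fixed
  seed, single thread and the same numpy version give bit-identical
  results. Everything runs in float64.
* Problem sizes in the test-suite and the reproduction script (n = 400
  scenario, rank-5 200×100 imputation fixture, 200-sample toys) are the
  package's packaged study conditions, chosen so a full run completes on
  a laptop CPU in minutes.
* Degenerate inputs have defined behaviour throughout: constant features
  scale to 0; features with < 2 observed values get variance 0; a fully
  missing column imputes to 0 with a warning; an all-zero mask, a
  non-finite loss, an empty sample intersection and an infeasible grid
  all raise with context.

## Known limitations

* The adversarial imputer's quality degrades with very long training
  (the game drifts); the default iteration budget reflects that.
* Grid search at the full factorial (324 points) with per-fold nesting
  is expensive; the single-point `GridSpec.small()` is the practical
  default for experimentation.
* The attention models need the strong-regularization defaults above to
  beat linear baselines at n in the hundreds; at larger n those defaults
  are likely conservative.
* Weight tying across encoders is deliberately not implemented;
  "identical parameters" is read as identical hyperparameters.
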