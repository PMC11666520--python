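# dmoit — denoised multi-omics integration

`dmoit` classifies samples from several omics layers measured on the same
individuals — e.g., mRNA abundance, DNA-methylation beta values and
ternary copy-number calls — in the regime that makes such data hard:
missing values, thousands of mostly noisy features, and class signal
split between *intra*-omics structure (within one layer) and
*inter*-omics structure (across layers). It is aimed at computational
biologists who want a complete, reproducible pipeline from delimited
matrices to cross-validated metrics and biomarker rankings.

Three ideas are combined:

1. **Adversarial imputation.** A generator proposes values for missing
   cells; a discriminator, aided by a partial *hint* of the true
   observedness mask M, predicts which cells were observed. The
   generator minimizes an adversarial term on missing cells plus
   α · reconstruction error on observed cells, and the final output is
   `M ⊙ X + (1 − M) ⊙ G(X̃, M)` — only missing cells are ever replaced.
2. **Bootstrap-stability feature selection.** The variance top-k filter
   is repeated over B bootstrap resamples of the samples; the m features
   most frequently selected survive. Features whose high variance is an
   artifact of a few samples do not.
3. **A dual multi-head self-attention extractor.** Each layer's feature
   vector is linearly embedded into a short token sequence and encoded
   with `softmax(QKᵀ/√d_k)V` attention heads
   (`MultiHead = Concat(head₁…head_h)W_O`). The `dmoit` architecture runs
   one encoder per layer (intra-omics) *and* a shared encoder on the
   concatenated layers (inter-omics) in parallel, concatenates the
   pooled outputs and classifies with an MLP. The single-path designs
   `m1` (per-layer only), `m2` (shared only) and `m3` (stacked) are
   included for comparison, plus logistic-regression / random-forest /
   SVM / XGBoost baselines, stratified 5-fold cross-validation with
   accuracy and weighted F1, full-factorial grid search, permutation
   feature importance, and an OLS sign-flip scan for cross-omics joint
   effects.

Because such data cannot ship with the package, a first-class synthetic
generator produces three heterogeneous layers with planted intra- and
inter-omics signal and MCAR missingness; every stage is tested against
it. See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/05_architecture_contrast.py` generates the packaged scenario
(400 samples; 500/400/200 features per layer; 45 informative features
carrying a 0.8 SD class shift; 35 cross-layer product pairs; 15% MCAR
missingness), mean-imputes the scaled continuous layers, and
cross-validates all four attention architectures and XGBoost:

```text
majority-class baseline accuracy: 0.545
     m1: accuracy 0.727 +/- 0.053, weighted F1 0.726
     m2: accuracy 0.728 +/- 0.044, weighted F1 0.724
     m3: accuracy 0.715 +/- 0.045, weighted F1 0.713
  dmoit: accuracy 0.745 +/- 0.049, weighted F1 0.744
    XGB: accuracy 0.828 +/- 0.051, weighted F1 0.827
```

Every attention architecture clears the majority-class baseline by well
over 0.15, and the dual-path `dmoit` is the best of the four — it can use
the cross-layer product signal the per-layer paths cannot represent.
`examples/04_adversarial_imputation.py` benchmarks the imputers on a
rank-5 matrix with 20% of cells hidden (RMSE on hidden cells only):

```text
hidden cells: 4000 of 20000
    zero: RMSE 0.5365
    mean: RMSE 0.1839
  median: RMSE 0.1842
     knn: RMSE 0.0765
    gain: RMSE 0.1212
```

The adversarial imputer beats the column-wise fills by exploiting
cross-feature structure (nearest-neighbour averaging is even stronger on
this perfectly low-rank fixture). The other examples cover simulation,
preprocessing and survival dichotomization, robust feature selection,
and biomarker ranking with the joint-effects scan — each prints what it
computes and what the numbers mean.

A thin command-line interface wraps the same functions:

```bash
dmoit simulate --n-samples 400 --seed 7 --outdir sim/
dmoit select --matrix sim/mRNA.tsv --kind continuous_nonneg -B 10 --out sel.tsv
dmoit impute --matrix scaled.tsv --method gain --out imputed.tsv
dmoit train --matrix imputed.tsv --kind continuous_unit \
            --labels sim/labels.tsv --arch dmoit --outdir out/
```

## Layout

```
src/dmoit/        library (data model, io, simulate, preprocess, rfs,
                  gain, models, train_eval, interpret, cli, autodiff core)
examples/         one short narrative script per capability
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py reproduction script
docs/methods.md   models, defaults, design rationale, limitations
```
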