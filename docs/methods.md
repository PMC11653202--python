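# Methods

## Overview

`morehg` classifies disease samples from several aligned omics layers
(e.g. mRNA expression, DNA methylation beta values, miRNA expression) and
ranks candidate biomarkers. The method has four stages:

1. **Preprocessing** — per modality: remove features containing NaN,
   filter low-variance features, keep the features with the largest
   one-way ANOVA F statistic, scale each feature to [0, 1].
2. **Hypergraph construction** — per modality, one hyperedge per sample
   connecting it to its nearest neighbours; the per-modality incidence
   matrices are concatenated column-wise into a single hypergraph over the
   shared samples.
3. **Network** — per-modality hypergraph-convolution encoders (MOHE) with
   omics-specific classification heads, fused across modalities by
   multi-head self-attention over the modality embeddings (MOSA) and a
   final linear classifier. Training is two-step: omics-specific
   pretraining, then joint optimization of the summed loss.
4. **Biomarker ranking** — zero-out ablation: each [0,1]-scaled feature is
   set to 0 everywhere, and the resulting drop of the held-out metric,
   summed over repeated trained runs, ranks features within a modality.

## Model

### Hypergraph and propagation operator

Each modality contributes `N` hyperedges over the same `N` samples: the
hyperedge centred on sample `j` contains `j` and its `k − 1` nearest other
samples (Euclidean distance on the scaled features by default, cosine
available). `k` is therefore the hyperedge cardinality *including* the
centre; `k = 1` degenerates to the identity incidence. The alternative
reading — `k` neighbours plus the centre — is available via
`include_self_in_k=False`. Distance ties break toward the smaller sample
index so duplicate profiles are handled deterministically.

With incidence `H ∈ {0,1}^{N×IN}` (`I` modalities), unit hyperedge weights
`W = I`, vertex degrees `D_v` and hyperedge degrees `D_e`, convolution uses
the symmetric normalized operator

```
G = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}.
```

`G` is symmetric positive semi-definite with spectral radius 1 and fixes
the vector `D_v^{1/2} 1`; the test suite asserts both numerically. Edge
weights are fixed at 1 — the framework carries `W` but nothing here learns
it. `G` is invariant to modality order because column permutations of `H`
cancel in `H (...) H^T`.

The hypergraph is built transductively over all samples supplied to a run
(training and held-out features; held-out labels are never used). This
follows the semi-supervised graph-learning convention for small cohorts.

### Encoders and attention fusion

One hypergraph convolution layer computes `X' = σ(G X Θ + b)`. Each
modality's encoder stacks `L` such layers (default `L = 2`) with dropout
between layers during training, mapping the selected features to an
embedding (default dimension 64), plus a linear omics-specific head
producing class logits. σ is LeakyReLU with slope 0.25.

For sample `j`, the `I` modality embeddings form a token matrix
`X̂_j ∈ R^{I×d}`. Each of `Z` heads (default 4) computes
`Q = X̂_j w_q + b_q`, `K`, `V` likewise (head dimension `d_f = d` by
default), the attention matrix

```
A_j = softmax( Q K^T / sqrt(d_f) )      (row-wise)
```

and the aggregation `V̂_j = A_j V ∈ R^{I×d_f}` — one fused vector per query
modality. Head outputs are concatenated, flattened over modalities and
heads (`I·d_f·Z`), and passed to a single linear classifier. The output
orientation of the aggregation and the flattening layout are conventions
of this implementation; only the row-softmax structure is intrinsic.

### Losses and two-step training

All losses are cross-entropy over *training* vertices only, using the mean
over samples (the raw per-sample sum differs by the constant factor `N`;
the mean keeps learning rates comparable across split sizes). Step one
trains each encoder + head alone on its own loss; step two optimizes every
parameter on

```
L = Σ_i L_omics^{(i)} + L_multi,
```

with the omics-specific heads active (not frozen). The logged loss report
stores each term per epoch, and the total is checked exactly against the
sum of its parts. An end-to-end mode skips step one. Ablation variants
swap the hypergraph encoder for a same-depth feed-forward encoder
(`nn_nn`, `nn_mosa`) and/or the attention fusion for a one-layer
feed-forward fusion of matching width (`nn_nn`, `mohe_nn`).

Optimization is Adam, learning rate 1e-3, defaults 200 pretraining and 500
joint epochs, uniform Glorot initialization, dropout 0.5 — all exposed in
`TrainConfig`/`ModelConfig`. The network and optimizer run on a small
in-package reverse-mode autodiff engine over numpy (`morehg.autodiff`),
whose gradients are verified against central finite differences in the
test suite. Every source of randomness (initialization, dropout masks,
splits, the generator) derives from explicit integer seeds, so identical
configuration and seed reproduce metrics and biomarker tables bitwise.

## Preprocessing details

- **Variance filter**: population (divide-by-`n`) variance, keeping
  features with variance *strictly greater* than the threshold. Defaults
  per modality: mRNA 0.1, methylation 0.001, miRNA 0 (constant features
  only). The dividing convention is a documented choice; thresholding is
  monotone in either convention.
- **ANOVA selection**: classical one-way F per feature. Zero within-group
  variance with positive between-group variance yields `F = +inf` (ranked
  first); an all-constant feature yields `F = 0`. Ties break toward the
  lower column index. Survivors keep their original column order.
- **Leakage**: selection and min/max statistics are fit on the training
  split only by default (`fit_on="train"`); held-out samples are
  transformed with the training statistics and clipped to [0, 1]. A
  transductive `fit_on="all"` mode exists because either convention
  appears in this literature; neither is asserted as canonical.
- **Splitting**: stratified 70/30 by default, five repeats. Per class,
  the training count is `round(train_fraction · n_c)` clamped so every
  class keeps at least one training and one test sample. Reported spread
  is the sample SD (ddof 1) across repeats.

## Synthetic data: what it emulates and what it does not

The generator produces `I` aligned sample × feature matrices. Class `c`
shifts each planted signal feature's mean to `c · effect_size · noise_sd`;
all features carry i.i.d. Gaussian noise with SD `noise_sd`; non-signal
features have mean 0 in every class; a configurable fraction of non-signal
features is set entirely to NaN to exercise the missing-feature stage.
Missing columns are drawn from the non-signal features only, so planted
signal remains recoverable downstream. Signal features occupy a documented
prefix of the feature ids (`<modality>_f0 …`), which is what lets tests
assert recovery.

A mean shift with spherical Gaussian noise is deliberately the simplest
structure that exercises every stage: ANOVA ranks by exactly the planted
contrast, kNN hyperedges pick up class locality, and ablation should
recover the planted set. It does **not** emulate realistic omics
marginals (negative-binomial counts, beta-distributed methylation),
feature correlation, batch effects, or label noise — so passing tests
demonstrate mechanical correctness and signal recovery under the model's
own assumptions, not performance on real cohorts.

Reference conditions used by the recovery checks: 300 samples, 2 classes,
3 × 200 features with 20 planted per modality, effect size 2, `k = 2`,
five repeats. Under these conditions the classifier is essentially
error-free, which has a knock-on effect on ablation: removing one of 20
redundant signal features flips no test prediction, so per-feature drops
are 0 and ranking falls to the documented index tie-break. The ablation
mechanism is therefore additionally measured at a deliberately hard
setting (160 samples, 5 planted of 60 features per modality, effect 0.8)
where accuracy is imperfect and planted features show clearly larger
drops than noise features (gap ≈ 0.1–0.3 summed over two runs).

## Biomarker ranking details

Ablation zeroes a feature's column for *all* samples (the transductive
forward includes every vertex) and evaluates F1 (binary) or macro F1
(multi-class) on the held-out vertices only. The trained model — including
its operator `G` — is frozen: the hypergraph is not rebuilt from ablated
features, so the measured drop isolates the feature's contribution to the
forward pass rather than conflating it with a graph change
(`rebuild_graph=True` restores the alternative). Negative drops are kept
and naturally rank last. Because feature selection is refit per repeat,
ranking operates over the union of selected features, a run contributing 0
for features it never saw.

## Problem sizes and numerical choices

- Recovery-scale runs in tests and the acceptance script use 60
  pretraining and 150 joint epochs; at the reference conditions the loss
  curves are flat well before these counts, and the library defaults
  (200/500) remain available for harder data.
- Softmax and cross-entropy are computed with max-subtraction; attention
  rows sum to 1 within 1e-6 under random stress, and entries can underflow
  to exactly 0 for extreme score gaps (the (0,1) openness holds in exact
  arithmetic only).
- Degenerate inputs fail loudly: zero-degree vertices or hyperedges,
  constant features reaching the scaler, non-finite losses, singleton
  classes under stratification, and `k` exceeding the sample count all
  raise with the offending index or id named.

## Known limitations

- Dense `N × N` linear algebra throughout: appropriate for cohort-scale
  data (hundreds to a few thousand samples), not for `N ≫ 10^4`.
- No probe-to-gene annotation step for methylation arrays; inputs are
  assumed feature-resolved.
- No imputation, batch correction, count normalization, learned hyperedge
  weights, or early stopping.
- The exact architecture of the original formulation of this model family
  (hidden sizes, activation, dropout) is not public in the main text this
  package follows; the defaults here are stated conventions of this
  implementation, config-exposed rather than claims.
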