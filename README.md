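# morehg

Multi-omics disease classification on fused kNN hypergraphs, with
attention-based modality integration and ablation-based biomarker
ranking.

## The problem

Cohort studies increasingly measure several molecular layers — mRNA
expression, DNA methylation, miRNA expression — on the same patients.
Each layer carries complementary signal about disease status or subtype,
and sample-to-sample similarity structure differs across layers. `morehg`
is for researchers who want to (i) classify patients from a handful of
aligned omics matrices at cohort scale (hundreds of samples), and (ii)
rank the features of each layer by how much the trained classifier
actually relies on them.

## The method

Per modality, every sample spawns one hyperedge containing itself and its
`k − 1` nearest neighbours; the per-modality incidence matrices
`H_i ∈ {0,1}^{N×N}` are concatenated into one hypergraph,
`H = [H_1 | … | H_I] ∈ {0,1}^{N×IN}`. With unit hyperedge weights and the
vertex/edge degree matrices `D_v`, `D_e`, hypergraph convolution uses the
symmetric normalized operator

```
G = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2},
X^{(l+1)} = σ( G X^{(l)} Θ^{(l)} ).
```

Each modality gets its own stack of such layers (a MOHE encoder) plus a
linear omics-specific head. The per-modality embeddings of a sample form
`I` tokens which `Z` self-attention heads fuse —
`A_j = softmax(Q K^T / √d_f)`, `V̂_j = A_j V` — before a final linear
classifier (the MOSA module). Training is two-step: each encoder is
pretrained on its own cross-entropy, then everything is optimized on the
total loss `L = Σ_i L_omics^{(i)} + L_multi`, computed on training
vertices only (transductive: held-out features enter the graph, held-out
labels never do).

Biomarkers: because inputs are min-max scaled to [0, 1], a feature is
removed by zeroing its column. The drop in held-out F1 (binary; macro F1
for multi-class), summed across the repeated trained runs, ranks the
features of each modality.

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

```python
import morehg as mh

# 300 samples, 2 classes, three modalities of 200 features,
# 20 planted signal features each at 2 SD mean shift
spec = mh.SyntheticSpec(n_samples=300, n_classes=2,
                        features_per_modality=(200, 200, 200),
                        signal_features_per_modality=(20, 20, 20),
                        effect_size=2.0, seed=11)
matrices, truth = mh.generate_multiomics(spec)

cfg = mh.ExperimentConfig()          # k=2, 2 conv layers, 4 heads
cfg.train.pretrain_epochs = 60
cfg.train.joint_epochs = 150
report, runs = mh.repeat_experiment(matrices, truth.labels, cfg)
print(report.summary())

table = mh.rank_biomarkers(runs, top_k=10)
top = table.top(10)
planted = set(truth.signal_feature_ids["mRNA"])
print(sum(f in planted for f in top[top.modality == "mRNA"].feature_id))
```

Output:

```
{'mean': {'acc': 1.0, 'f1': 1.0, 'auc': 1.0}, 'sd': {'acc': 0.0, 'f1': 0.0, 'auc': 0.0}}
10
```

At this effect size the planted signal is strong enough that all five
70/30 repeats classify the held-out samples perfectly (mean ACC/F1/AUC
1.0 ± 0.0), and all 10 of the top-10 ablation-ranked mRNA features are
planted signal features. Harder settings (smaller effects, fewer planted
features) give graded accuracies and graded ablation drops; see
`docs/methods.md`.

The same pipeline runs from the shell:

```
morehg simulate --config sim.yaml --out-dir data/
morehg evaluate --config run.yaml --out results/ --save-runs
morehg biomarkers --runs-dir results/ --top-k 10 --out biomarkers.csv
morehg sweep-k --config run.yaml --k-values 1,2,3,5 --out sweep.csv
```

where the YAML config holds flat keys (`data:` modality→CSV paths,
`labels:`, `k:`, `n_select:`, `pretrain_epochs:`, …; every run directory
receives a `manifest.json` with the resolved config and input hashes).
Matrices are CSV/TSV with a sample-id column and feature-id header.

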