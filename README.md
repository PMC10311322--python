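# pikn — pathway-induced kernel networks for interpretable (multi-)omics classification

`pikn` trains neural classifiers on molecular measurement matrices (gene
expression, copy-number calls, ...) whose internal structure is readable in
pathway terms, for people who need to know *why* a sample was classified,
not only *how well* — e.g. stratifying cancer cohorts by relapse risk while
reporting which signalling pathways drove the call.

## The model

For each biological pathway r with symmetric normalized graph Laplacian
`L_r` over its member features, the pathway-induced kernel between two
samples restricted to those features is the bilinear form

    K_r(x, z) = x^T L_r z .

A Nyström-type kernel layer embeds a sample into the span of q trainable
anchor points `z_1..z_q` per pathway,

    psi_r(x) = (K_ZZ + eps I)^{-1/2} [K_r(x, z_1), ..., K_r(x, z_q)]^T ,

which is the explicit parametrization of the orthogonal projection of the
sample's kernel image onto that subspace. Anchors are initialized with
k-means++ and trained end to end. Two heads make the models interpretable:

- **Pooling head (global):** `y = sum_r w_r max(psi_r)`; the signed,
  trained `w_r` form a pathway signature of the model itself.
- **Gated-attention head (local):** the p embeddings are a bag of
  instances; attention weights
  `a_r ∝ exp(w^T (tanh(V psi_r) ⊙ sigm(U psi_r)))` are per-sample pathway
  importances, and the attention-pooled bag is classified linearly.

A multi-omics composite max-pools each modality's pathway embeddings into a
modality vector and fuses the modalities with gated attention. Training
uses Adam (batch 32, 200 epochs) and a class-balanced cross-entropy based
on the effective number of samples per class. There is no autodiff
dependency: all gradients, including the eigendecomposition backward pass
of the Gram inverse square root, are analytic and finite-difference tested.

## Worked example

Simulate pathway-structured expression data in which 2 of 10 pathways carry
a class-conditional mean shift, train a pooling model, and read its
signature:

```python
import numpy as np
from pikn import (SimulationConfig, simulate_pathways, simulate_expression,
                  pathway_laplacian, PoolingKernelNet, TrainConfig, train,
                  auroc, global_signature)

cfg = SimulationConfig(n_samples=500, n_pathways=10, informative_set=(0, 1),
                       effect_size=1.5, seed=7)
pathways = simulate_pathways(cfg.n_pathways, cfg.pathway_size_range, seed=7)
data = simulate_expression(cfg, pathways)
ds = data.modalities["expression"]

laplacians = [pathway_laplacian(pw) for pw in pathways]
idx = np.random.default_rng(7).permutation(ds.n_samples)
train_ds, test_ds = ds.subset(idx[100:]), ds.subset(idx[:100])

model = PoolingKernelNet(laplacians, q=30, init_seed=7)
model, history = train(model, train_ds, TrainConfig(seed=7, anchor_init_seed=7))
print(f"final training loss: {history[-1]:.3f}")
print(f"held-out auROC:      {auroc(model.predict_scores(test_ds), test_ds.labels):.3f}")

signature = global_signature(model)
print("pathways ranked by |weight|:", signature.ranking()[:3])
print("true informative pathways:  ", data.informative_ids)
```

Output:

```
final training loss: 0.042
held-out auROC:      0.856
pathways ranked by |weight|: ['pw01', 'pw00', 'pw03']
true informative pathways:   ['pw00', 'pw01']
```

The two largest-|w| pathways are exactly the informative ones — the
signature recovers the planted signal — and the model separates held-out
classes well above chance. For per-sample explanations, train an
`AttentionKernelNet` and call `local_attention`; for expression + CNA
fusion, `MultiOmicsKernelNet`.

## Command line

The `pikn` CLI wraps the library: `simulate`, `train`, `evaluate`, `cv`,
`interpret`, `scaling`. Runs are configured by a YAML file
(see `pikn.config.RunConfig`; unknown keys are rejected and a resolved copy
is written next to the outputs):

```yaml
data: sim/expression.tsv          # or {expression: ..., cna: ...}
labels: sim/labels.tsv
pathways: sim/pathways.gmt        # or laplacian_dir: with precomputed TSVs
edge_dir: sim/edges               # optional per-pathway edge lists
model: {type: pooling, q: 30}
train: {epochs: 200, seed: 1}
output_dir: run1
```

```
pikn simulate --out sim --n-samples 500 --seed 1
pikn train config.yaml
pikn interpret run1/checkpoint.zip --out run1
```

Input formats: sample × feature TSV matrices, GMT gene sets, 3-column edge
lists, or precomputed Laplacian TSVs (node-name header + index). Signature
exports are CSV (`pathway_id,weight`) or JSON; attention maps are long-form
CSV (`sample_id,pathway_id,attention,score,predicted_label,true_label`) or
JSON.

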