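# nichemil

Interpretable multiple-instance learning of **cellular recruitment** from
spatially resolved transcriptomics (SRT).

## The problem

Tissues recruit cells selectively: T cells infiltrate some tumor
neighborhoods and avoid others, immune cells home to damaged cardiomyocytes,
and so on. SRT platforms (VisiumHD, CosMx WTX, Slide-tag, Visium, Xenium)
record both gene expression and position for every cell or bin, so the rules
of recruitment are in principle readable from the data — which genes
expressed by the **resident** cell type (tumor cells, cardiomyocytes, ...)
attract or repel an **engaging** cell type (T cells, B cells, macrophages,
...)? `nichemil` answers that question with a model whose every parameter has
a direct biological reading, and provides the downstream analyses that
interrogate the resulting gene ranking.

## The model

Recruitment is cast as multiple-instance learning. Each circular
neighborhood of resident cells (radius *r*, default 50 µm) is a **bag**; its
instances are the resident cells inside the circle with their expression
profiles `x_i` and distances `d_i` to the center; the bag label `y ∈ {0, 1}`
is the biological ground truth — whether an engaging cell sits at the
center. The network has three readable modules:

1. **Distance attention.** A kernel `e_i = κ(d_i)` computed from distance
   alone (a one-input MLP with softplus output, or an exponential kernel
   `−d/ℓ` with learned length-scale ℓ), normalized per bag:
   `a_i = softmax(e)`, so `Σ_i a_i = 1`. This models the spatial decay of
   signaling.
2. **Gene gate.** A per-gene multiplicative gate `g = σ(γ) ∈ (0,1)^G`
   selecting influential expression features.
3. **Linear gene weighting.** With the attention-pooled neighborhood
   pseudo-profile `z = Σ_i a_i x_i`,

   `P(y = 1) = σ( wᵀ(g ⊙ z) + b )`.

Training minimizes binary cross-entropy with L1/L2 penalties on `w` (Adam,
early stopping on validation loss). Because the prediction is strictly
linear in the gated pseudo-profile, the signed per-gene **recruitment
score** `s_g = w_g · g_g · sd(z_g)` reads off each gene's attractive
(positive) or repulsive (negative) potential on a scale comparable across
genes. Downstream, the package contrasts *predicted* with *observed*
infiltration (recruitment–engagement duality), runs differential expression
of engaging cells between predicted-positive and predicted-negative regions,
and offers the rank statistics used to validate gene rankings
(hypergeometric top-set overlap, decile binning with a Jonckheere–Terpstra
trend test, Spearman correlation between score vectors).

A seeded synthetic-tissue generator with planted attractant/repellent genes
makes every stage testable without downloading data.

## Worked example

```python
import nichemil as nm

cfg = nm.SimConfig(seed=1)                      # 2x2 mm slab, 200 genes, 10+10 planted
ds, truth = nm.simulate(cfg)
ds = nm.normalize(nm.qc_filter(ds, min_genes=1), target_total=1e4)
bags = nm.build_bags(ds, "resident", "engaging", radius=50.0, min_instances=5, seed=1)
train, val, test = nm.split_bags(bags, (0.7, 0.15, 0.15), seed=1)
model, history = nm.train(train, val, nm.ModelConfig(seed=1))
scores = nm.recruitment_scores(model, bags)

pred = nm.predict(test, model)
print("bags:", len(bags), "| held-out AUROC:",
      round(nm.auroc(pred["label"], pred["probability"]), 3))
print(scores.table.sort_values("rank").head(3).to_string(index=False))
print(nm.recovery_metrics(truth, scores))
```

prints

```
bags: 1280 | held-out AUROC: 0.855
 gene    score  rank direction
g0138 0.564973     1   attract
g0017 0.427214     2   attract
g0047 0.379012     3   attract
{'auroc_planted': 0.9736..., 'sign_accuracy': 1.0, 'spearman_beta': 0.8671...}
```

The generator planted 10 attractant and 10 repellent genes (effect ±1 on the
log-odds of engaging-cell placement, 25 µm signaling decay). The trained
model separates planted from null genes by |score| with AUROC 0.97, gets
every planted gene's sign right, and its top-ranked gene is a planted
attractant. The held-out AUROC (0.855) is bag-level prediction accuracy on a
spatially held-out block.

The same pipeline is available as a CLI:

```bash
nichemil simulate --seed 7 --outdir sim
nichemil score    --seed 7 --input sim/dataset.csv --cells sim/cells.tsv --outdir run
nichemil report   --scores run/scores.tsv --truth sim/truth.json --outdir rep --seed 7
```

Real data enter through `read_dataset` (10x-style MTX triplet + coordinate
table, dense CSV/TSV, or `.h5ad` with `obsm["spatial"]`), followed by
`qc_filter`, `normalize`, `score_signatures` and percentile (multi-cell
spots) or argmax-with-abstention (high-definition) cell typing.

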