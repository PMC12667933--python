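# Methods

## Model

### Bags

A bag is the circular neighborhood of **resident** cells around a center
point; its binary label records whether an **engaging** cell sits at the
center. Positive bags are centered on engaging cells; negative bags are
centered on resident cells that have no engaging cell within an exclusion
distance (default: the bag radius, so a negative bag's circle can never
contain an engaging cell). Instances are resident cells only; a cell typed
as both resident and engaging counts as engaging and never appears as an
instance, which is conservative against label leakage.

Two deliberate choices in bag construction:

* **Negative centers come from resident cells**, not arbitrary grid points,
  so both classes sample neighborhoods inside the resident tissue region.
* **A negative bag's center cell is excluded from its own instance list.**
  Including it would give every negative bag a guaranteed zero-distance
  instance that positive bags almost never have; a trained model can convert
  that purely geometric asymmetry into class-separating signal (the
  attention-pooled profile of negative bags becomes a single skewed draw
  rather than an average), inflating apparent accuracy with no gene-level
  meaning. For a homogeneous point pattern, removing the center cell makes
  the negative-bag geometry distributionally identical to positive bags (the
  pattern seen from one of its points, minus that point, looks like the
  pattern seen from a uniform location).

Defaults: radius 50 µm, at least 5 instances per bag, at most 256 (nearest
first, recorded in provenance), negatives subsampled to the positive count
(engaging cells are typically the rarer type). Neighborhood search uses a
k-d tree; its results are contract-tested against exhaustive O(n²) scans.

### Network

For a bag with instance expression `x_i` (library-size-normalized, log1p)
and distances `d_i`:

* attention logits `e_i = κ(d_i / r)`; two kernels are available —
  `learned_mlp` (default), a one-input MLP with `kernel_hidden` (default 8)
  tanh units and a softplus output, and `exponential`, `−d/ℓ` with
  `ℓ = softplus(ρ)` learned (one interpretable length-scale);
* attention `a = softmax(e)` (sums to one per bag; the forward pass asserts
  this);
* pseudo-profile `z = Σ_i a_i x_i`;
* gate `g = σ(γ)`, logit `wᵀ(g ⊙ z) + b`, probability through a sigmoid.

Distances are scaled by the bag radius before the kernel so the MLP operates
on inputs in [0, 1]. Parameters: `w` and the gate start at `0` and
`γ = 2` (gates ~0.88, near-open); kernel weights are small seeded Gaussians;
the exponential length-scale starts at r/2. The model is deliberately
minimal: attention depends on distance only, and the gene weighting is
strictly linear so that `w` is directly interpretable.

### Training

Mean binary cross-entropy plus `λ₁‖w‖₁ + λ₂‖w‖₂²` (defaults 1e-4 / 1e-5),
minimized with Adam (learning rate 1e-3, batch 64, at most 500 epochs),
early-stopped when validation BCE fails to improve for 10 epochs; the
best-validation-epoch parameters are returned. Gradients are analytic
(NumPy); with a fixed seed, data order, and single-threaded execution,
training is bit-reproducible.

### Train/validation/test split

The split is stratified by label with exact per-label counts, but bags are
assigned to splits as **contiguous runs along a Morton space-filling curve**
of their centers (the seed rotates the curve's starting point), not
uniformly at random. Neighboring bags share instance cells; with a uniform
random split, a fitted weight direction that memorizes instance-level noise
in the training bags transfers to held-out bags through those shared cells
and inflates held-out AUROC far above chance even when labels carry no gene
signal — and no weight penalty can remove the effect, because the leak lives
in the direction of `w`, not its magnitude. Spatially coherent blocks
confine the sharing to block boundaries; on null simulations the held-out
AUROC then sits at chance. The cost is slightly pessimistic accuracy
estimates (a spatial block is a harder generalization target than an
interleaved sample), which is the honest side to err on for spatial data.

### Recruitment scores

`s_g = w_g · g_g · sd(z_g)`, with `sd` taken across a reference bag
collection (population standard deviation). The `sd` factor puts genes of
different expression scales on a common footing. Rank 1 is the strongest
attractant; ties break by gene symbol; a gene with `w_g = 0` scores 0 and is
assigned direction "none".

## Preprocessing and typing

Cells with fewer than `min_genes` (default 100) detected genes are dropped;
counts are scaled to a common per-cell total (default 1e4) and
log1p-transformed. Cell-type signature scores are the summed normalized
expression of a panel's detected marker genes. Two typing rules:

* **percentile** (multi-cell spots): a spot is positive for a type iff its
  score strictly exceeds the type's 75th percentile (linear-interpolation
  quantile; ties at the threshold are negative). Spots may be positive for
  several types.
* **argmax with abstention** (high-definition): a cell takes its top-scoring
  type unless the runner-up is within τ (default 10%) of the top score, in
  which case it is left unlabeled. This is a programmatic stand-in for
  expert review of ambiguous bins, not a reconstruction of any particular
  manual workflow.

Gene filtering for the model keeps the k genes with highest mean normalized
expression over resident cells, datasets weighted equally.

## Downstream analyses

* **Infiltration map** (`predict_regions`): every resident cell with enough
  resident neighbors gets an unlabeled bag and a probability; predicted to
  infiltrate iff p ≥ 0.5.
* **Duality DE** (`duality_de`): engaging cells attach to the nearest
  evaluated point within the radius; genes expressed in <5% of engaging
  cells in both groups are dropped; per gene a two-sided Wilcoxon rank-sum
  compares normalized expression between groups, logFC uses a 1e-9
  pseudocount, and Benjamini–Hochberg adjusts across tested genes. The
  two-sided choice follows the convention that directionless comparisons
  are two-way.
* **Rank-sum p-values** are exact (full enumeration of group assignments,
  tie-safe) when both groups have ≤ 8 observations, otherwise the
  tie-corrected normal approximation.
* **Top-set overlap**: top m = round(fraction·N, half-up) genes per ranked
  list; inclusive upper-tail hypergeometric p for each pair.
* **Jonckheere–Terpstra trend**: the statistic counts between-group
  concordances (ties half). The null is evaluated by exhaustive permutation
  enumeration when the number of distinct group assignments is ≤ 200 000,
  otherwise by the tie-corrected normal approximation — exhaustive
  enumeration is infeasible beyond that regardless of sample size, so the
  switch is on enumeration cost, not on n alone. Two-sided p is
  2·min(tails) capped at 1; constant data returns 1.
* Small rule classifiers: protein localization (keep confidence > 4 strictly;
  any surviving extracellular entry → extracellular; else intracellular;
  no surviving entry → uncertain), tissue-region calls (a cell is outside
  the target region iff the target-type fraction within 30 µm, itself
  included, is strictly below 50%), and developmental trends over
  (fetal, childhood, adult) stage means (decreasing iff fetal is the strict
  maximum and adult the strict minimum; increasing for the mirror case;
  otherwise non-directional).

## Synthetic-data generator

The generator emulates a tissue slab: resident cells uniform in a
2000×2000 µm arena (n = 3000 by default, ~6 resident neighbors per 50 µm
circle — a realistic near-single-cell bin density); per-gene negative
binomial counts (dispersion 2.0) with log-normal means (µ = 0, σ = 1 on the
log scale); 200 genes of which 10 attract and 10 repel with effect β = 1 on
the log-odds; 3000 uniform candidate sites. Each candidate site s receives

    u(s) = β₀ + Σ_i e^{−d_i/ℓ} · Σ_g β_g (x_ig − x̄_g) / Σ_i e^{−d_i/ℓ}

over resident cells within r = 50 µm, with decay length ℓ = 25 µm, on
normalized log1p expression; an engaging cell appears with probability
σ(u(s)). Two generator-design points:

* the distance weights are normalized (divide by Σ e^{−d/ℓ}), so the
  potential is insensitive to local cell density and isolates gene effects
  from cell-count effects;
* the gene term uses **centered** expression, so β₀ = −1 is the baseline
  log-odds at average local expression. Without centering, the random
  expression scale of whichever genes happen to be planted shifts the
  placement rate arbitrarily (in some draws essentially every candidate, or
  none, receives an engaging cell), and the scenario no longer yields the
  intended roughly-balanced bag collections.

Engaging cells draw counts from the same count model as residents, i.e. the
generator plants **no intrinsic expression difference** in engaging cells —
only their placement carries signal. What the generator does *not* emulate:
tissue morphology, platform noise (bin bleed-through, segmentation error),
batch effects, 3D structure, or correlated gene programs. Passing recovery
tests therefore show that the estimator works when its generative
assumptions hold; they do not certify performance on real tissue.

## Evaluation

`recovery_metrics` compares learned scores with the planted truth:
planted-vs-null discrimination by |score| (pairwise-concordance AUROC), the
fraction of planted genes with the correct sign, and the Spearman
correlation between score and coefficient over planted genes (with only two
coefficient values ±β, its ceiling under perfect separation is ≈ 0.867, not
1). Null calibration repeats the pipeline with β = 0 and expects chance-level
held-out and recovery AUROC. `scripts/acceptance.py` runs three signal seeds
and five null seeds of the default scenario (a few seconds per run on one
CPU) and writes the aggregated metrics as JSON.

## Known limitations

* The architecture is a reference design chosen for minimal capacity and
  full interpretability; richer instance encoders or cross-type attention
  are out of scope.
* Joint multi-dataset training pools bags without a batch covariate; strong
  batch effects between datasets are not modeled.
* Bag labels reflect presence within the sampled field; engaging cells just
  outside the section boundary are unobservable.
* The spatially blocked split assumes recruitment rules are stationary
  across the tissue section; strong regional heterogeneity would make the
  held-out estimate a between-region generalization measure.
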