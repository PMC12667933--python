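"""The interpretable multiple-instance network and its training loop.

Architecture (three named modules, all directly readable from the learned
parameters):

1. *Distance attention* — an attention logit ``e_i = kappa(d_i)`` computed
   from each instance's distance to the bag center alone, through either a
   one-input MLP with softplus output (``learned_mlp``) or an exponential
   kernel ``-d / ell`` with a learned length-scale (``exponential``).
   Attention ``a_i = softmax(e)`` so the weights sum to one per bag.
2. *Gene feature gate* — a per-gene multiplicative gate ``g = sigmoid(gamma)``
   in (0, 1) selecting influential expression features.
3. *Gene weighting* — a strictly linear signed weight vector ``w`` over the
   attention-pooled bag pseudo-profile ``z = sum_i a_i x_i``:
   ``p = sigmoid(w . (g * z) + b)``.

Training minimizes mean binary cross-entropy plus an L1/L2 penalty on ``w``
with Adam, early-stopping on validation loss. Because the prediction is
linear in the gated pseudo-profile, the signed per-gene *recruitment score*
``w_g * g_g * sd(z_g)`` reads off each gene's attractive (positive) or
repulsive (negative) potential on a common scale.

The network is small enough that forward and backward passes are written
directly in NumPy; all randomness is seeded, training is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit

from .bags import Bag, BagCollection

__all__ = [
    "ModelConfig",
    "RecruitmentModel",
    "RecruitmentScores",
    "forward",
    "train",
    "predict",
    "recruitment_scores",
    "auroc",
]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class ModelConfig:
    """Hyperparameters of the recruitment model.

    ``radius`` is carried over from the bag collection and used only to put
    distances on a unit scale before the kernel. ``l1_gene``/``l2_gene``
    penalize the signed gene weights (sparsity keeps the gene ranking
    interpretable). ``patience`` is the early-stopping window in epochs.
    """

    radius: float = 50.0
    distance_kernel: str = "learned_mlp"  # or "exponential"
    kernel_hidden: int = 8
    l1_gene: float = 1e-4
    l2_gene: float = 1e-5
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l1_gene < 0 or self.l2_gene < 0 or self.learning_rate <= 0:
            raise ValueError("rates and penalties must be non-negative")
        if not 0 <= self.patience < self.max_epochs:
            raise ValueError("patience must satisfy 0 <= patience < max_epochs")
        if self.distance_kernel not in ("learned_mlp", "exponential"):
            raise ValueError(f"unknown distance_kernel {self.distance_kernel!r}")


@dataclass
class RecruitmentModel:
    """Learned parameters: distance-attention kernel, per-gene gate, signed
    per-gene weights and bias."""

    config: ModelConfig
    gene_subset: list[str]
    params: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        G = len(self.gene_subset)
        if self.params["w"].shape != (G,) or self.params["gamma"].shape != (G,):
            raise ValueError("w / gamma length must match gene_subset")
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite parameter {k!r}")

    @property
    def gate(self) -> np.ndarray:
        """Per-gene gate values g in (0,1)."""
        return expit(self.params["gamma"])

    def attention_logits(self, d: np.ndarray) -> np.ndarray:
        """Kernel kappa(d): attention logit from distance (micrometers)."""
        t = np.asarray(d, dtype=float) / self.config.radius
        p = self.params
        if self.config.distance_kernel == "learned_mlp":
            h = np.tanh(t[..., None] * p["u"] + p["a"])
            return _softplus(h @ p["v"] + p["c"][0])
        ell = _softplus(p["rho"][0])
        return -t * (self.config.radius / ell)

    def save(self, outdir: str | Path) -> None:
        """JSON metadata + binary parameter blob."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "gene_subset": self.gene_subset}
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(outdir / "params.npz", **self.params)

    @classmethod
    def load(cls, outdir: str | Path) -> "RecruitmentModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        with np.load(outdir / "params.npz") as blob:
            params = {k: blob[k] for k in blob.files}
        return cls(ModelConfig(**meta["config"]), meta["gene_subset"], params)


@dataclass
class RecruitmentScores:
    """The interpretable output: one signed score and rank per gene.

    Positive scores mark attractants, negative scores repellents; rank 1 is
    the strongest attractant, ties broken by gene symbol.
    """

    table: pd.DataFrame  # columns: gene, score, rank, direction

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..G")
        if not np.all(np.isfinite(self.table["score"])):
            raise ValueError("non-finite score")

    @classmethod
    def from_scores(cls, genes: Iterable[str], scores: np.ndarray) -> "RecruitmentScores":
        genes = list(genes)
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        rank = np.empty(len(genes), dtype=int)
        rank[order] = np.arange(1, len(genes) + 1)
        direction = np.where(scores > 0, "attract", np.where(scores < 0, "repel", "none"))
        df = pd.DataFrame({"gene": genes, "score": scores, "rank": rank, "direction": direction})
        return cls(df)

    def as_series(self) -> pd.Series:
        return pd.Series(self.table["score"].to_numpy(), index=self.table["gene"].to_numpy())

    def ranked_genes(self) -> list[str]:
        """Gene symbols in rank order (1 = strongest attractant first)."""
        return self.table.sort_values("rank")["gene"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.sort_values("rank").to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RecruitmentScores":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _forward_padded(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    X: np.ndarray,
    D: np.ndarray,
    mask: np.ndarray,
) -> dict[str, np.ndarray]:
    """Batched forward pass on padded arrays; returns all intermediates."""
    T = D / config.radius
    if config.distance_kernel == "learned_mlp":
        h = np.tanh(T[..., None] * params["u"] + params["a"])  # B x I x H
        pre = h @ params["v"] + params["c"][0]  # B x I
        e = _softplus(pre)
    else:
        ell = _softplus(params["rho"][0])
        pre = None
        h = None
        e = -D / ell
    e = np.where(mask, e, -np.inf)
    emax = np.max(e, axis=1, keepdims=True)
    ex = np.exp(e - emax)
    ex = np.where(mask, ex, 0.0)
    A = ex / ex.sum(axis=1, keepdims=True)  # attention, rows sum to 1
    Z = np.einsum("bi,big->bg", A, X)  # bag pseudo-profiles
    g = expit(params["gamma"])
    s = Z @ (params["w"] * g) + params["b"][0]
    p = expit(s)
    return {"T": T, "h": h, "pre": pre, "A": A, "Z": Z, "g": g, "s": s, "p": p}


def _backward_padded(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    X: np.ndarray,
    D: np.ndarray,
    mask: np.ndarray,
    y: np.ndarray,
    cache: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Gradient of mean BCE + L1/L2(w) w.r.t. every parameter."""
    B = X.shape[0]
    A, Z, g, p = cache["A"], cache["Z"], cache["g"], cache["p"]
    ds = (p - y) / B  # dL/dlogit
    grads: dict[str, np.ndarray] = {}
    grads["b"] = np.array([ds.sum()])
    dwg = ds @ Z  # gradient w.r.t. the product w*g
    grads["w"] = dwg * g + config.l1_gene * np.sign(params["w"]) + 2 * config.l2_gene * params["w"]
    grads["gamma"] = dwg * params["w"] * g * (1.0 - g)
    dZ = ds[:, None] * (params["w"] * g)[None, :]  # B x G
    dA = np.einsum("bg,big->bi", dZ, X)
    de = A * (dA - np.sum(A * dA, axis=1, keepdims=True))  # softmax backward
    if config.distance_kernel == "learned_mlp":
        dpre = de * expit(cache["pre"])  # softplus backward
        dpre = np.where(mask, dpre, 0.0)
        h = cache["h"]
        grads["v"] = np.einsum("bi,bih->h", dpre, h)
        grads["c"] = np.array([dpre.sum()])
        dz1 = dpre[..., None] * params["v"] * (1.0 - h * h)
        grads["u"] = np.einsum("bih,bi->h", dz1, cache["T"])
        grads["a"] = dz1.sum(axis=(0, 1))
    else:
        rho = params["rho"][0]
        ell = _softplus(rho)
        de = np.where(mask, de, 0.0)
        # e = -D/ell, de/drho = (D/ell^2) * sigmoid(rho)
        grads["rho"] = np.array([float(np.sum(de * D)) / ell**2 * expit(rho)])
    return grads


def _init_params(config: ModelConfig, n_genes: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {
        "w": np.zeros(n_genes),
        "gamma": np.full(n_genes, 2.0),  # gates start near-open (g ~ 0.88)
        "b": np.zeros(1),
    }
    if config.distance_kernel == "learned_mlp":
        H = config.kernel_hidden
        params["u"] = rng.normal(0.0, 1.0, H)
        params["a"] = np.zeros(H)
        params["v"] = rng.normal(0.0, 1.0 / np.sqrt(H), H)
        params["c"] = np.array([0.5])
    else:
        # softplus(rho) = ell; start at half the bag radius
        ell0 = config.radius / 2.0
        params["rho"] = np.array([ell0 + np.log1p(-np.exp(-ell0))])
    return params


def forward(bag: Bag, model: RecruitmentModel, expr: np.ndarray) -> float:
    """Probability that an engaging cell sits at the bag center.

    ``expr`` is the instance-feature matrix the bag indexes into (cells x
    gene_subset, normalized). Invariant to instance ordering.
    """
    if bag.n_instances == 0:
        raise ValueError("empty bag")
    X = expr[bag.instance_index][None, ...]
    if X.shape[2] != len(model.gene_subset):
        raise ValueError(
            f"bag features ({X.shape[2]} genes) do not match model ({len(model.gene_subset)})"
        )
    D = bag.distances[None, :]
    mask = np.ones_like(D, dtype=bool)
    cache = _forward_padded(model.params, model.config, X, D, mask)
    a_sum = float(cache["A"].sum())
    assert abs(a_sum - 1.0) < 1e-9, "attention weights must sum to 1"
    return float(cache["p"][0])


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train(
    train_bags: BagCollection,
    val_bags: BagCollection,
    config: ModelConfig,
) -> tuple[RecruitmentModel, pd.DataFrame]:
    """Fit the model by mini-batch Adam on BCE + L1/L2(w), early-stopping on
    validation BCE; returns the best-validation-epoch parameters and a
    per-epoch train/val loss history. Deterministic under ``config.seed``."""
    for name, bc in (("train", train_bags), ("validation", val_bags)):
        labs = set(bc.labels.tolist())
        if labs != {0, 1}:
            raise ValueError(f"{name} split must contain both classes, has labels {sorted(labs)}")
    if train_bags.gene_subset != val_bags.gene_subset:
        raise ValueError("train and validation gene subsets differ")

    G = len(train_bags.gene_subset)
    params = _init_params(config, G)
    Xtr, Dtr, Mtr, ytr = train_bags.padded_arrays()
    Xva, Dva, Mva, yva = val_bags.padded_arrays()

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    rng = np.random.default_rng(config.seed + 1)
    n = len(train_bags)
    best_val = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_epoch = -1
    wait = 0
    history = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, Db, Mb, yb = Xtr[idx], Dtr[idx], Mtr[idx], ytr[idx]
            cache = _forward_padded(params, config, Xb, Db, Mb)
            penalty = config.l1_gene * np.abs(params["w"]).sum() + config.l2_gene * np.sum(
                params["w"] ** 2
            )
            loss = _bce(cache["p"], yb) + penalty
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}"
                )
            train_losses.append(loss)
            grads = _backward_padded(params, config, Xb, Db, Mb, yb, cache)
            t += 1
            for k in params:
                gk = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                params[k] = params[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        val_cache = _forward_padded(params, config, Xva, Dva, Mva)
        val_loss = _bce(val_cache["p"], yva)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in params.items()}
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    model = RecruitmentModel(config, list(train_bags.gene_subset), best_params)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def predict(bags: BagCollection, model: RecruitmentModel) -> pd.DataFrame:
    """Per-bag engagement probability and hard label at threshold 0.5."""
    if bags.gene_subset != model.gene_subset:
        raise ValueError("bag gene subset does not match model")
    X, D, mask, y = bags.padded_arrays()
    cache = _forward_padded(model.params, model.config, X, D, mask)
    p = cache["p"]
    return pd.DataFrame(
        {"probability": p, "predicted": (p >= 0.5).astype(int), "label": y.astype(int)}
    )


def attention_weights(bags: BagCollection, model: RecruitmentModel) -> list[np.ndarray]:
    """Learned attention a_i per bag (each sums to 1), in instance order."""
    X, D, mask, _ = bags.padded_arrays()
    cache = _forward_padded(model.params, model.config, X, D, mask)
    return [cache["A"][k, : b.n_instances] for k, b in enumerate(bags.bags)]


def bag_profiles(bags: BagCollection, model: RecruitmentModel) -> np.ndarray:
    """Attention-pooled pseudo-profiles z (bags x genes)."""
    X, D, mask, _ = bags.padded_arrays()
    return _forward_padded(model.params, model.config, X, D, mask)["Z"]


def recruitment_scores(
    model: RecruitmentModel, reference_bags: BagCollection
) -> RecruitmentScores:
    """Signed per-gene scores ``w_g * g_g * sd(z_g)``.

    The standard deviation of the pseudo-profile component across the
    reference bags puts genes of different expression scales on a common
    footing, so scores are comparable across genes.
    """
    if len(reference_bags) == 0:
        raise ValueError("reference_bags must be nonempty")
    Z = bag_profiles(reference_bags, model)
    sd = Z.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate reference bags: zero variance for every gene")
    scores = model.params["w"] * model.gate * sd
    return RecruitmentScores.from_scores(model.gene_subset, scores)


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the rank formula (ties count 1/2)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs both classes")
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
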