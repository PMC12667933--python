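"""Construction of labeled multiple-instance bags from typed spatial data.

A bag is a circular neighborhood of resident (recruiting) cells. Positive
bags are centered on engaging cells (the cell type whose localization is
being explained); negative bags are centered on resident cells that have no
engaging cell within an exclusion distance. The bag label is therefore the
biological ground truth — the presence or absence of an engaging cell at the
bag's center — and the instances are the resident cells inside the circle,
never the engaging type itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .srt_io import SpatialDataset

__all__ = ["Bag", "BagCollection", "filter_genes", "build_bags", "split_bags"]


class ClassAbsenceError(ValueError):
    """No positive or no negative bag candidates exist."""


@dataclass
class Bag:
    """One labeled spatial neighborhood (the MIL training unit)."""

    center: tuple[float, float]
    label: int  # 1 = engaging cell present at center
    instance_index: np.ndarray  # rows into the source dataset
    distances: np.ndarray  # micrometers from each instance to the center
    dataset_id: str

    def __post_init__(self) -> None:
        self.instance_index = np.asarray(self.instance_index, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.label not in (0, 1):
            raise ValueError(f"bag label must be 0 or 1, got {self.label}")
        if len(self.instance_index) != len(self.distances):
            raise ValueError("instance_index and distances length mismatch")

    @property
    def n_instances(self) -> int:
        return len(self.instance_index)


@dataclass
class BagCollection:
    """A set of bags over one expression space.

    ``expr`` holds the instance feature rows (cells x gene_subset, normalized
    log1p values) that ``Bag.instance_index`` points into, so a collection is
    self-contained once built and can pool several datasets.
    """

    bags: list[Bag]
    radius: float
    gene_subset: list[str]
    resident_type: str
    engaging_type: str
    expr: np.ndarray
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        if self.expr.shape[1] != len(self.gene_subset):
            raise ValueError("expr columns != gene_subset length")
        for b in self.bags:
            if b.n_instances and b.instance_index.max() >= self.expr.shape[0]:
                raise ValueError("bag references an invalid cell index")

    def __len__(self) -> int:
        return len(self.bags)

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags], dtype=int)

    def subset(self, idx: Sequence[int]) -> "BagCollection":
        return BagCollection(
            bags=[self.bags[i] for i in idx],
            radius=self.radius,
            gene_subset=self.gene_subset,
            resident_type=self.resident_type,
            engaging_type=self.engaging_type,
            expr=self.expr,
            cell_ids=self.cell_ids,
            provenance=dict(self.provenance),
        )

    def padded_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Pack bags into padded arrays (X: B x I x G, D: B x I, mask, y)."""
        if not self.bags:
            raise ValueError("empty bag collection")
        imax = max(b.n_instances for b in self.bags)
        B, G = len(self.bags), len(self.gene_subset)
        X = np.zeros((B, imax, G), dtype=np.float64)
        D = np.zeros((B, imax), dtype=np.float64)
        mask = np.zeros((B, imax), dtype=bool)
        y = self.labels.astype(np.float64)
        for k, b in enumerate(self.bags):
            n = b.n_instances
            X[k, :n] = self.expr[b.instance_index]
            D[k, :n] = b.distances
            mask[k, :n] = True
        return X, D, mask, y

    # -- serialization ------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Two-file TSV serialization plus gene subset and provenance."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows, inst_rows = [], []
        for k, b in enumerate(self.bags):
            rows.append(
                {
                    "bag_id": k,
                    "dataset_id": b.dataset_id,
                    "center_x": b.center[0],
                    "center_y": b.center[1],
                    "label": b.label,
                    "n_instances": b.n_instances,
                }
            )
            for i, d in zip(b.instance_index, b.distances):
                inst_rows.append(
                    {"bag_id": k, "cell_id": str(self.cell_ids[i]), "distance_um": d}
                )
        pd.DataFrame(rows).to_csv(outdir / "bags.tsv", sep="\t", index=False)
        pd.DataFrame(inst_rows).to_csv(outdir / "instances.tsv", sep="\t", index=False)
        (outdir / "gene_subset.txt").write_text("\n".join(self.gene_subset) + "\n")
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------


def filter_genes(
    datasets: Sequence[SpatialDataset], resident_type: str, k: int
) -> list[str]:
    """Top-``k`` genes by mean normalized expression over resident cells.

    Datasets contribute with equal weight (unweighted average of per-dataset
    means over the shared gene universe). Deterministic order: descending
    mean, ties broken by gene symbol.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    universe = None
    for ds in datasets:
        s = set(ds.gene_ids.tolist())
        universe = s if universe is None else (universe & s)
    universe = sorted(universe or set())
    if k > len(universe):
        raise ValueError(f"k={k} exceeds shared gene universe of {len(universe)}")
    means = np.zeros(len(universe))
    for ds in datasets:
        if not ds.normalized:
            raise ValueError(f"dataset {ds.dataset_id!r} is not normalized")
        resident = ds.cells_of_type(resident_type)
        if resident.size == 0:
            raise ValueError(f"no {resident_type!r} cells in dataset {ds.dataset_id!r}")
        cols = ds.gene_index(universe)
        means += ds.dense_expr()[np.ix_(resident, cols)].mean(axis=0)
    means /= len(datasets)
    # sort: descending mean, then ascending symbol
    order = sorted(range(len(universe)), key=lambda i: (-means[i], universe[i]))
    return [universe[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# bag construction
# ---------------------------------------------------------------------------


def build_bags(
    ds: SpatialDataset,
    resident_type: str,
    engaging_type: str,
    radius: float = 50.0,
    min_instances: int = 5,
    neg_exclusion: float | None = None,
    balance: bool = True,
    seed: int = 0,
    gene_subset: Sequence[str] | None = None,
    max_instances: int = 256,
) -> BagCollection:
    """Build labeled bags from one typed, normalized dataset.

    Positive bags: one per engaging-type cell whose circle of ``radius``
    contains at least ``min_instances`` resident cells. Negative bags:
    centers sampled (seeded, without replacement) from resident cells with no
    engaging cell within ``neg_exclusion`` (default: ``radius``) and enough
    resident neighbors. A cell labeled both resident and engaging counts as
    engaging and never appears as an instance (conservative against label
    leakage). When ``balance`` is set, negatives are subsampled to the
    positive count. Bags keep at most ``max_instances`` nearest instances.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if neg_exclusion is None:
        neg_exclusion = radius
    if neg_exclusion < 0:
        raise ValueError("neg_exclusion must be >= 0")
    if not ds.normalized:
        raise ValueError("build_bags expects normalized expression")

    engaging = ds.cells_of_type(engaging_type)
    engaging_set = set(engaging.tolist())
    resident = np.array(
        [i for i in ds.cells_of_type(resident_type) if i not in engaging_set], dtype=int
    )
    if resident.size == 0:
        raise ClassAbsenceError(f"no {resident_type!r} cells available as instances")

    genes = list(gene_subset) if gene_subset is not None else ds.gene_ids.astype(str).tolist()
    expr = ds.dense_expr()[:, ds.gene_index(genes)]

    res_tree = cKDTree(ds.coords[resident])
    eng_tree = cKDTree(ds.coords[engaging]) if engaging.size else None

    def _instances(center: np.ndarray, exclude: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        local = res_tree.query_ball_point(center, r=radius)
        idx = resident[np.asarray(local, dtype=int)] if local else np.empty(0, dtype=int)
        if exclude is not None:
            idx = idx[idx != exclude]
        d = np.linalg.norm(ds.coords[idx] - center, axis=1) if idx.size else np.empty(0)
        order = np.lexsort((idx, d))  # nearest first, index tiebreak for determinism
        idx, d = idx[order], d[order]
        if len(idx) > max_instances:
            idx, d = idx[:max_instances], d[:max_instances]
        return idx, d

    bags: list[Bag] = []
    for e in engaging:
        center = ds.coords[e]
        idx, d = _instances(center)
        if len(idx) >= min_instances:
            bags.append(Bag(tuple(center), 1, idx, d, ds.dataset_id))
    n_pos = len(bags)
    if n_pos == 0:
        raise ClassAbsenceError("no positive bag candidates (no engaging cell has enough resident neighbors)")

    neg_candidates = []
    for r in resident:
        center = ds.coords[r]
        if eng_tree is not None and eng_tree.query_ball_point(center, r=neg_exclusion):
            continue
        # The center cell is excluded from its own instance list: a guaranteed
        # zero-distance self-instance would make the two classes geometrically
        # distinguishable regardless of gene expression.
        idx, d = _instances(center, exclude=r)
        if len(idx) >= min_instances:
            neg_candidates.append(Bag(tuple(center), 0, idx, d, ds.dataset_id))
    if not neg_candidates:
        raise ClassAbsenceError("no negative bag candidates (no resident cell clear of engaging cells)")

    rng = np.random.default_rng(seed)
    if balance and len(neg_candidates) > n_pos:
        chosen = rng.choice(len(neg_candidates), size=n_pos, replace=False)
        neg_candidates = [neg_candidates[i] for i in np.sort(chosen)]
    bags.extend(neg_candidates)

    prov = {
        "dataset_id": ds.dataset_id,
        "radius": radius,
        "min_instances": min_instances,
        "neg_exclusion": neg_exclusion,
        "balance": balance,
        "max_instances": max_instances,
        "seed": seed,
        "n_positive": n_pos,
        "n_negative": len(neg_candidates),
    }
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True).encode()
    ).hexdigest()[:16]
    return BagCollection(
        bags=bags,
        radius=radius,
        gene_subset=genes,
        resident_type=resident_type,
        engaging_type=engaging_type,
        expr=expr,
        cell_ids=ds.cell_ids,
        provenance=prov,
    )


def merge_collections(collections: Sequence[BagCollection]) -> BagCollection:
    """Pool bags from several datasets sharing one gene subset."""
    first = collections[0]
    for c in collections[1:]:
        if c.gene_subset != first.gene_subset:
            raise ValueError("collections have different gene subsets")
    bags: list[Bag] = []
    exprs, cids = [], []
    offset = 0
    for c in collections:
        for b in c.bags:
            bags.append(
                Bag(b.center, b.label, b.instance_index + offset, b.distances, b.dataset_id)
            )
        exprs.append(c.expr)
        cids.append(c.cell_ids)
        offset += c.expr.shape[0]
    return BagCollection(
        bags=bags,
        radius=first.radius,
        gene_subset=first.gene_subset,
        resident_type=first.resident_type,
        engaging_type=first.engaging_type,
        expr=np.vstack(exprs),
        cell_ids=np.concatenate(cids),
        provenance={"merged_from": [c.provenance for c in collections]},
    )


def _morton_order(centers: np.ndarray) -> np.ndarray:
    """Order points along a Morton (Z-order) space-filling curve."""
    lo = centers.min(axis=0)
    span = np.maximum(centers.max(axis=0) - lo, 1e-12)
    q = np.floor((centers - lo) / span * 65535).astype(np.uint64)
    key = np.zeros(len(centers), dtype=np.uint64)
    for bit in range(16):
        key |= ((q[:, 0] >> np.uint64(bit)) & np.uint64(1)) << np.uint64(2 * bit)
        key |= ((q[:, 1] >> np.uint64(bit)) & np.uint64(1)) << np.uint64(2 * bit + 1)
    return np.argsort(key, kind="stable")


def split_bags(
    bc: BagCollection, fractions: tuple[float, float, float], seed: int = 0
) -> tuple[BagCollection, BagCollection, BagCollection]:
    """Label-stratified, spatially blocked train/val/test split.

    Splits are disjoint, their union is the input, per-label counts follow
    ``fractions`` exactly, and the partition is reproducible under ``seed``.
    Within each label stratum, bags are ordered along a space-filling curve of
    their centers and assigned to splits as contiguous runs (the seed rotates
    the curve's starting point). Neighboring bags share instance cells, so a
    uniformly random split would let instance-level noise memorized from the
    training bags leak into held-out bags; spatially coherent blocks keep
    that overlap to the block boundaries.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    labels = bc.labels
    centers = np.array([b.center for b in bc.bags], dtype=float)
    parts: list[list[int]] = [[], [], []]
    for lab in (0, 1):
        stratum = np.where(labels == lab)[0]
        if stratum.size and stratum.size < 3:
            raise ValueError(f"label-{lab} stratum has {stratum.size} bags (< 3)")
        order = stratum[_morton_order(centers[stratum])]
        order = np.roll(order, int(rng.integers(len(order))))
        n = len(order)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        cuts = [order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]]
        for p, c in zip(parts, cuts):
            p.extend(c.tolist())
    return tuple(bc.subset(sorted(p)) for p in parts)  # type: ignore[return-value]
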