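"""Reading, validation, preprocessing and cell typing of spatially resolved
transcriptomics (SRT) data.

The in-memory container is :class:`SpatialDataset`: a cells x genes expression
matrix with 2D coordinates in micrometers and optional multi-label cell-type
tags. Three on-disk formats are supported: a 10x-style MTX triplet (plus a
coordinate table), a dense CSV/TSV, and an AnnData ``.h5ad`` container with
coordinates in ``obsm["spatial"]``.

Preprocessing follows the standard single-cell recipe: drop low-quality
cells (< ``min_genes`` detected genes), library-size normalize each cell to a
common target total, and log1p-transform. Cell types are assigned from marker
signature panels: the per-cell signature score is the summed normalized
expression of the panel's detected marker genes; for low-definition (multi-cell
spot) platforms a spot is called positive for a type when its score strictly
exceeds the per-type 75th-percentile (multi-label allowed), while for
high-definition data an argmax-with-abstention rule gives a single label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger("nichemil")

__all__ = [
    "SpatialDataset",
    "SignaturePanel",
    "read_dataset",
    "write_dataset",
    "write_cell_metadata",
    "qc_filter",
    "normalize",
    "score_signatures",
    "assign_types_percentile",
    "assign_types_argmax",
]


class FormatError(ValueError):
    """A companion file is missing or a file cannot be parsed."""


class ValidationError(ValueError):
    """Dataset contents violate a :class:`SpatialDataset` invariant."""


class EmptyDatasetError(ValueError):
    """An operation removed every cell."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialDataset:
    """Cells/bins with 2D spatial coordinates and gene expression.

    Parameters
    ----------
    cell_ids
        Unique string identifiers, one per cell (row).
    coords
        ``(n_cells, 2)`` float array of (x, y) positions in micrometers.
    expr
        ``(n_cells, n_genes)`` non-negative matrix; raw counts unless
        ``normalized`` is True, in which case values are log1p of
        library-size-scaled counts.
    gene_ids
        Unique gene symbols, one per column.
    type_labels
        Optional per-cell set of cell-type tags (multi-label allowed).
    dataset_id
        Batch tag used to keep provenance when several datasets are pooled.
    normalized
        Whether :func:`normalize` has been applied.
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    expr: np.ndarray
    gene_ids: np.ndarray
    type_labels: list[set[str]] | None = None
    dataset_id: str = "dataset"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if not sparse.issparse(self.expr):
            self.expr = np.asarray(self.expr, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n, g = self.expr.shape
        if len(self.cell_ids) != n or self.coords.shape != (n, 2):
            raise ValidationError(
                f"inconsistent shapes: expr {self.expr.shape}, "
                f"{len(self.cell_ids)} cell ids, coords {self.coords.shape}"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} expression columns"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = np.where(~np.isfinite(self.coords).all(axis=1))[0]
            raise ValidationError(f"non-finite coordinates at rows {bad[:5].tolist()}")
        vals = self.expr.data if sparse.issparse(self.expr) else self.expr
        if vals.size and float(np.min(vals)) < 0:
            raise ValidationError("negative expression values")
        for name, arr in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            uniq, counts = np.unique(arr.astype(str), return_counts=True)
            if len(uniq) != len(arr):
                dups = uniq[counts > 1][:5].tolist()
                raise ValidationError(f"duplicate {name} ids: {dups}")
        if self.type_labels is not None and len(self.type_labels) != n:
            raise ValidationError("type_labels length != number of cells")

    # -- convenience -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def dense_expr(self) -> np.ndarray:
        if sparse.issparse(self.expr):
            return np.asarray(self.expr.todense(), dtype=float)
        return self.expr

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices of ``genes``; raises KeyError for absent symbols."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Row indices of cells carrying ``cell_type`` among their labels."""
        if self.type_labels is None:
            raise ValidationError("dataset has no type labels")
        return np.array(
            [i for i, tags in enumerate(self.type_labels) if cell_type in tags],
            dtype=int,
        )

    def subset_cells(self, rows: np.ndarray) -> "SpatialDataset":
        rows = np.asarray(rows, dtype=int)
        labels = (
            [self.type_labels[i] for i in rows] if self.type_labels is not None else None
        )
        return SpatialDataset(
            cell_ids=self.cell_ids[rows],
            coords=self.coords[rows],
            expr=self.expr[rows],
            gene_ids=self.gene_ids,
            type_labels=labels,
            dataset_id=self.dataset_id,
            normalized=self.normalized,
        )


@dataclass
class SignaturePanel:
    """Marker-gene panels: cell type -> non-empty list of gene symbols."""

    panels: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for cell_type, genes in self.panels.items():
            if len(genes) == 0:
                raise ValidationError(f"empty marker panel for type {cell_type!r}")
            if not all(isinstance(g, str) for g in genes):
                raise ValidationError(f"non-string gene symbol in panel {cell_type!r}")

    def types(self) -> list[str]:
        return list(self.panels.keys())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_csv_dense(path: Path) -> SpatialDataset:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    required = {"cell_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    for col in ("x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric coordinate in column {col} at row "
                f"{int(np.where(bad)[0][0])}"
            )
    gene_cols = [c for c in df.columns if c not in required]
    return SpatialDataset(
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        coords=df[["x_um", "y_um"]].to_numpy(dtype=float),
        expr=df[gene_cols].to_numpy(dtype=float),
        gene_ids=np.array(gene_cols, dtype=object),
        dataset_id=path.stem,
    )


def _read_mtx_triplet(path: Path) -> SpatialDataset:
    path = Path(path)
    matrix_f = path / "matrix.mtx"
    barcodes_f = path / "barcodes.tsv"
    features_f = path / "features.tsv"
    coords_f = path / "coords.tsv"
    for f in (matrix_f, barcodes_f, features_f, coords_f):
        if not f.exists():
            raise FormatError(f"missing companion file: {f}")
    mat = sparse.csr_matrix(mmread(matrix_f)).T  # stored genes x cells, 10x style
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).to_numpy()
    feats = pd.read_csv(features_f, sep="\t", header=None)
    genes = feats.iloc[:, -1].astype(str).to_numpy(dtype=object)
    coords = pd.read_csv(coords_f, sep="\t", dtype={"barcode": str})
    if not {"barcode", "x_um", "y_um"}.issubset(coords.columns):
        raise FormatError(f"{coords_f}: expected columns barcode, x_um, y_um")
    coords = coords.set_index("barcode")
    missing = [b for b in barcodes if b not in coords.index]
    if missing:
        raise FormatError(f"barcodes without coordinates: {missing[:5]}")
    xy = coords.loc[barcodes, ["x_um", "y_um"]]
    bad = xy.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        raise FormatError(
            f"{coords_f}: non-numeric coordinate at row {int(np.where(bad)[0][0])}"
        )
    return SpatialDataset(
        cell_ids=barcodes.astype(object),
        coords=xy.to_numpy(dtype=float),
        expr=mat,
        gene_ids=genes,
        dataset_id=path.name,
    )


def _read_h5ad(path: Path) -> SpatialDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise FormatError(f"{path}: no obsm['spatial'] coordinate slot")
    labels = None
    if "type_labels" in adata.obs:
        labels = [
            set(str(s).split(";")) if str(s) else set() for s in adata.obs["type_labels"]
        ]
    return SpatialDataset(
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        coords=np.asarray(adata.obsm["spatial"], dtype=float)[:, :2],
        expr=adata.X if sparse.issparse(adata.X) else np.asarray(adata.X, dtype=float),
        gene_ids=adata.var_names.to_numpy(dtype=object),
        type_labels=labels,
        dataset_id=str(adata.uns.get("dataset_id", Path(path).stem)),
        normalized=bool(adata.uns.get("normalized", False)),
    )


_READERS = {"csv_dense": _read_csv_dense, "mtx_triplet": _read_mtx_triplet, "h5ad": _read_h5ad}


def read_dataset(path: str | Path, format: str) -> SpatialDataset:
    """Read a :class:`SpatialDataset` from disk.

    ``format`` is one of ``mtx_triplet`` (a directory with matrix.mtx,
    barcodes.tsv, features.tsv and coords.tsv), ``csv_dense`` (cells x genes
    with cell_id/x_um/y_um columns) or ``h5ad``. Row and column order follow
    file order. The returned dataset has ``normalized=False`` unless the h5ad
    container says otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    try:
        reader = _READERS[format]
    except KeyError:
        raise FormatError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    return reader(path)


def write_dataset(ds: SpatialDataset, path: str | Path, format: str) -> None:
    """Write ``ds`` in one of the supported on-disk formats."""
    path = Path(path)
    if format == "csv_dense":
        df = pd.DataFrame(ds.dense_expr(), columns=ds.gene_ids.astype(str))
        df.insert(0, "y_um", ds.coords[:, 1])
        df.insert(0, "x_um", ds.coords[:, 0])
        df.insert(0, "cell_id", ds.cell_ids.astype(str))
        df.to_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",", index=False)
    elif format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mat = sparse.coo_matrix(ds.expr).T  # genes x cells on disk
        mmwrite(str(path / "matrix.mtx"), mat)
        pd.Series(ds.cell_ids.astype(str)).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame({"id": ds.gene_ids.astype(str), "name": ds.gene_ids.astype(str)}).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {"barcode": ds.cell_ids.astype(str), "x_um": ds.coords[:, 0], "y_um": ds.coords[:, 1]}
        ).to_csv(path / "coords.tsv", sep="\t", index=False)
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=ds.expr if sparse.issparse(ds.expr) else np.asarray(ds.expr),
            obs=pd.DataFrame(index=ds.cell_ids.astype(str)),
            var=pd.DataFrame(index=ds.gene_ids.astype(str)),
        )
        adata.obsm["spatial"] = ds.coords
        if ds.type_labels is not None:
            adata.obs["type_labels"] = [";".join(sorted(t)) for t in ds.type_labels]
        adata.uns["dataset_id"] = ds.dataset_id
        adata.uns["normalized"] = bool(ds.normalized)
        adata.write_h5ad(path)
    else:
        raise FormatError(f"unknown format {format!r}")


def write_cell_metadata(ds: SpatialDataset, path: str | Path) -> None:
    """Write the cell-metadata TSV: cell_id, x_um, y_um, semicolon-joined labels."""
    labels = (
        [";".join(sorted(t)) for t in ds.type_labels]
        if ds.type_labels is not None
        else [""] * ds.n_cells
    )
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids.astype(str),
            "x_um": ds.coords[:, 0],
            "y_um": ds.coords[:, 1],
            "type_labels": labels,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def qc_filter(ds: SpatialDataset, min_genes: int) -> SpatialDataset:
    """Keep cells with at least ``min_genes`` genes detected (nonzero counts).

    Gene set and cell order are unchanged. Raises if every cell is removed.
    """
    if ds.normalized:
        raise ValidationError("qc_filter operates on raw counts, not normalized data")
    if sparse.issparse(ds.expr):
        detected = np.asarray((ds.expr > 0).sum(axis=1)).ravel()
    else:
        detected = (ds.expr > 0).sum(axis=1)
    keep = np.where(detected >= min_genes)[0]
    if keep.size == 0:
        raise EmptyDatasetError(
            f"qc_filter(min_genes={min_genes}) removed all {ds.n_cells} cells"
        )
    return ds.subset_cells(keep)


def normalize(ds: SpatialDataset, target_total: float = 1e4) -> SpatialDataset:
    """Library-size normalize each cell to ``target_total``, then log1p."""
    if ds.normalized:
        raise ValidationError("dataset is already normalized")
    X = ds.dense_expr()
    totals = X.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"zero-total cell(s) {ds.cell_ids[zero[:5]].tolist()}; run qc_filter first"
        )
    X = np.log1p(X * (target_total / totals)[:, None])
    return replace(ds, expr=X, normalized=True)


def score_signatures(ds: SpatialDataset, panel: SignaturePanel) -> pd.DataFrame:
    """Per-cell signature scores: summed normalized expression of detected
    marker genes, one column per cell type.

    Panel genes absent from the dataset are dropped with a logged warning; a
    type with no detected marker at all raises.
    """
    if not ds.normalized:
        raise ValidationError("score_signatures expects normalized data")
    X = ds.dense_expr()
    present = set(ds.gene_ids.tolist())
    scores = {}
    for cell_type, genes in panel.panels.items():
        detected = [g for g in genes if g in present]
        missing = [g for g in genes if g not in present]
        if missing:
            logger.warning(
                "panel %r: %d marker gene(s) not detected and dropped: %s",
                cell_type, len(missing), missing,
            )
        if not detected:
            raise ValidationError(f"no marker gene of type {cell_type!r} detected")
        scores[cell_type] = X[:, ds.gene_index(detected)].sum(axis=1)
    return pd.DataFrame(scores, index=ds.cell_ids.astype(str))


def assign_types_percentile(scores: pd.DataFrame, q: float = 0.75) -> list[set[str]]:
    """Multi-label typing for low-definition (multi-cell spot) data.

    For each type independently, a cell is positive iff its signature score
    strictly exceeds the ``q``-quantile (linear interpolation) of that type's
    score distribution; ties at the threshold are negative. A spot may be
    positive for several types.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite signature score")
    labels: list[set[str]] = [set() for _ in range(len(scores))]
    for j, cell_type in enumerate(scores.columns):
        col = vals[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"constant signature score for type {cell_type!r}; no positive cells",
                stacklevel=2,
            )
            continue
        thr = np.quantile(col, q)  # linear interpolation
        for i in np.where(col > thr)[0]:
            labels[i].add(str(cell_type))
    return labels


def assign_types_argmax(scores: pd.DataFrame, tau: float = 0.10) -> list[set[str]]:
    """Single-label typing for high-definition data, with abstention.

    Each cell gets the type with the highest signature score, unless the top
    two scores differ by less than ``tau`` times the top score, in which case
    the cell is left unlabeled (ambiguous identity, discarded downstream).
    """
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite signature score")
    cols = [str(c) for c in scores.columns]
    labels: list[set[str]] = []
    for row in vals:
        order = np.argsort(row)[::-1]
        top, second = row[order[0]], (row[order[1]] if len(row) > 1 else -np.inf)
        if top <= 0 or (len(row) > 1 and top - second < tau * abs(top)):
            labels.append(set())
        else:
            labels.append({cols[order[0]]})
    return labels
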