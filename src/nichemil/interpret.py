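"""Downstream analyses of a trained recruitment model.

Two families of operations live here. The first consumes the model directly:
probabilistic infiltration maps over the resident-cell regions
(:func:`predict_regions`) and the recruitment–engagement duality analysis —
differential expression of engaging cells found in predicted-to-infiltrate
versus predicted-not-to-infiltrate regions (:func:`duality_de`), plus the
expression-weighted signature score built from those fold changes. The second
family is rank/overlap/trend statistics used to interrogate the gene ranking:
Spearman correlation between score vectors, hypergeometric overlap of top
gene sets, decile binning with a Jonckheere-Terpstra trend test, and small
rule-based classifiers (protein localization, tissue-region calls,
developmental expression trends).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .bags import BagCollection
from .mil import RecruitmentModel, RecruitmentScores, _forward_padded
from .srt_io import SpatialDataset

__all__ = [
    "predict_regions",
    "duality_de",
    "signature_score",
    "score_correlation",
    "top_set_overlap",
    "decile_trend",
    "jonckheere_test",
    "rank_sum_test",
    "peptide_burden",
    "geneset_bag_comparison",
    "classify_localization",
    "classify_region",
    "developmental_trend",
]


# ---------------------------------------------------------------------------
# infiltration maps and duality differential expression
# ---------------------------------------------------------------------------


def predict_regions(
    ds: SpatialDataset,
    model: RecruitmentModel,
    radius: float | None = None,
    min_instances: int = 5,
    resident_type: str = "resident",
    engaging_type: str = "engaging",
) -> pd.DataFrame:
    """Score every evaluable resident-cell neighborhood with the model.

    For each resident cell with at least ``min_instances`` resident neighbors
    within ``radius`` (default: the model's radius), an unlabeled bag is built
    at that cell and scored. Returns one row per evaluated point: cell_id,
    x_um, y_um, probability, predicted_infiltrate (p >= 0.5), and
    observed_engaging_within_radius.
    """
    if radius is None:
        radius = model.config.radius
    if not ds.normalized:
        raise ValueError("predict_regions expects normalized data")
    resident = ds.cells_of_type(resident_type)
    engaging = ds.cells_of_type(engaging_type)
    resident = np.array([i for i in resident if i not in set(engaging.tolist())], dtype=int)
    if resident.size == 0:
        raise ValueError("no resident cells to evaluate")

    expr = ds.dense_expr()[:, ds.gene_index(model.gene_subset)]
    res_xy = ds.coords[resident]
    tree = cKDTree(res_xy)
    eng_tree = cKDTree(ds.coords[engaging]) if engaging.size else None

    rows = []
    neighbor_lists = tree.query_ball_point(res_xy, r=radius)
    for k, local in enumerate(neighbor_lists):
        idx = resident[np.asarray(local, dtype=int)]
        if len(idx) < min_instances:
            continue
        center = res_xy[k]
        d = np.linalg.norm(ds.coords[idx] - center, axis=1)
        X = expr[idx][None, ...]
        cache = _forward_padded(
            model.params, model.config, X, d[None, :], np.ones((1, len(idx)), dtype=bool)
        )
        p = float(cache["p"][0])
        observed = bool(eng_tree.query_ball_point(center, r=radius)) if eng_tree else False
        rows.append(
            {
                "cell_id": str(ds.cell_ids[resident[k]]),
                "x_um": center[0],
                "y_um": center[1],
                "probability": p,
                "predicted_infiltrate": p >= 0.5,
                "observed_engaging_within_radius": observed,
            }
        )
    if not rows:
        raise ValueError("no evaluable points (min_instances too high for this layout)")
    return pd.DataFrame(rows)


def duality_de(
    ds: SpatialDataset,
    regions: pd.DataFrame,
    engaging_type: str = "engaging",
    min_cells: int = 10,
    radius: float | None = None,
    detection_fraction: float = 0.05,
) -> pd.DataFrame:
    """Differential expression of engaging cells between predicted-positive
    and predicted-negative regions.

    Engaging cells are attached to the nearest evaluated resident point
    within ``radius`` (default: the largest attachment distance is the
    evaluation radius is unknown here, so the caller's radius should match
    the one used for :func:`predict_regions`); unattached cells are dropped.
    Genes expressed in fewer than ``detection_fraction`` of engaging cells in
    both groups are excluded. Per gene: two-sided Wilcoxon rank-sum,
    logFC = log((mean+ + eps) / (mean- + eps)) with eps = 1e-9 (positive =
    higher in predicted-to-infiltrate), Benjamini-Hochberg across tested genes.
    """
    if radius is None:
        radius = 50.0
    if not ds.normalized:
        raise ValueError("duality_de expects normalized data")
    engaging = ds.cells_of_type(engaging_type)
    if engaging.size == 0:
        raise ValueError(f"no {engaging_type!r} cells")
    pts = regions[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    dist, nearest = tree.query(ds.coords[engaging], k=1)
    attached = dist <= radius
    flags = regions["predicted_infiltrate"].to_numpy(dtype=bool)[nearest[attached]]
    cells = engaging[attached]
    pos_cells, neg_cells = cells[flags], cells[~flags]
    for name, grp in (("predicted-positive", pos_cells), ("predicted-negative", neg_cells)):
        if len(grp) < min_cells:
            raise ValueError(
                f"{name} group has {len(grp)} engaging cells (< min_cells={min_cells})"
            )

    X = ds.dense_expr()
    Xp, Xn = X[pos_cells], X[neg_cells]
    det_p = (Xp > 0).mean(axis=0)
    det_n = (Xn > 0).mean(axis=0)
    tested = np.where((det_p >= detection_fraction) | (det_n >= detection_fraction))[0]
    eps = 1e-9
    rows = []
    for j in tested:
        mp, mn = float(Xp[:, j].mean()), float(Xn[:, j].mean())
        p = rank_sum_test(Xp[:, j], Xn[:, j])
        rows.append(
            {
                "gene": str(ds.gene_ids[j]),
                "mean_predicted_pos": mp,
                "mean_predicted_neg": mn,
                "logFC": float(np.log((mp + eps) / (mn + eps))),
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows)
    table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return table.sort_values("pvalue", kind="stable").reset_index(drop=True)


def signature_score(cell_expr: Mapping[str, float], logfc: Mapping[str, float]) -> float:
    """Sum over shared genes of expression x logFC (tumor-reactive signature).

    Genes missing on either side are skipped; an empty intersection raises.
    """
    shared = [g for g in cell_expr if g in logfc]
    if not shared:
        raise ValueError("no shared genes between expression and logFC")
    return float(sum(cell_expr[g] * logfc[g] for g in shared))


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def score_correlation(scores_a: RecruitmentScores, scores_b: RecruitmentScores) -> float:
    """Spearman correlation (average-rank ties) between two score vectors over
    their shared genes; requires at least 10 shared genes."""
    a, b = scores_a.as_series(), scores_b.as_series()
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    return float(stats.spearmanr(a.loc[shared], b.loc[shared]).statistic)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def top_set_overlap(
    rank_lists: Mapping[str, Sequence[str]], top_fraction: float = 0.25
) -> pd.DataFrame:
    """Pairwise overlap of the top fraction of each ranked gene list, with an
    upper-tail hypergeometric p per pair.

    All lists must rank the same universe of N genes. The top-set size is
    m = round(top_fraction * N) (half-up); p is the probability of an overlap
    at least as large when drawing m of N with m marked (inclusive tail).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    names = list(rank_lists)
    if len(names) < 2:
        raise ValueError("need at least two ranked lists")
    universe = set(rank_lists[names[0]])
    for n in names[1:]:
        if set(rank_lists[n]) != universe:
            raise ValueError(f"list {n!r} ranks a different gene universe")
    N = len(universe)
    m = _round_half_up(top_fraction * N)
    tops = {n: set(list(rank_lists[n])[:m]) for n in names}
    rows = []
    for na, nb in combinations(names, 2):
        overlap = len(tops[na] & tops[nb])
        p = float(stats.hypergeom.sf(overlap - 1, N, m, m))
        rows.append({"list_a": na, "list_b": nb, "overlap": overlap, "m": m, "N": N, "pvalue": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------


@dataclass
class TrendResult:
    statistic: float
    p_increasing: float
    p_decreasing: float
    p_two_sided: float
    method: str
    bins: list[list[str]] | None = None


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT = sum over ordered group pairs of Mann-Whitney counts (ties = 1/2)."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x, y = groups[i][:, None], groups[j][None, :]
            jt += float(np.sum(x < y) + 0.5 * np.sum(x == y))
    return jt


def _jt_exact(values: np.ndarray, sizes: list[int], observed: float) -> tuple[float, float]:
    """Exact permutation tails by exhaustive enumeration of group assignments."""
    n = len(values)
    ge = 0
    le = 0
    total = 0

    def rec(remaining: tuple[int, ...], k: int, chosen: list[np.ndarray]) -> None:
        nonlocal ge, le, total
        if k == len(sizes):
            jt = _jt_statistic(chosen)
            total += 1
            if jt >= observed - 1e-9:
                ge += 1
            if jt <= observed + 1e-9:
                le += 1
            return
        if k == len(sizes) - 1:
            rec((), k + 1, chosen + [values[list(remaining)]])
            return
        for combo in combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(combo))
            rec(rest, k + 1, chosen + [values[list(combo)]])

    rec(tuple(range(n)), 0, [])
    return ge / total, le / total


def _jt_normal(groups: Sequence[np.ndarray], observed: float) -> tuple[float, float]:
    """Tie-corrected normal approximation of the JT null distribution."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ni = np.array([len(g) for g in groups], dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (N**2 - np.sum(ni**2)) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(ni * (ni - 1) * (2 * ni + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(ni * (ni - 1) * (ni - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = np.sum(ni * (ni - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
    var = term1 + term2 + term3
    if var <= 0:  # constant data
        return 1.0, 1.0
    z = (observed - mean) / np.sqrt(var)
    return float(stats.norm.sf(z)), float(stats.norm.cdf(z))


def _n_arrangements(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    total = 1
    for s in sizes:
        total *= comb(n, s)
        n -= s
    return total


def jonckheere_test(
    groups: Sequence[np.ndarray], max_exact: int = 200_000
) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Uses exhaustive permutation enumeration when the number of distinct group
    assignments is at most ``max_exact`` (which covers all small problems),
    otherwise the tie-corrected normal approximation. The two-sided p is
    2 * min(tails), capped at 1; constant data returns p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    observed = _jt_statistic(groups)
    sizes = [len(g) for g in groups]
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        mean = (len(values) ** 2 - sum(s**2 for s in sizes)) / 4.0
        return TrendResult(mean, 1.0, 1.0, 1.0, "degenerate")
    if _n_arrangements(sizes) <= max_exact:
        p_inc, p_dec = _jt_exact(values, sizes, observed)
        method = "exact"
    else:
        p_inc, p_dec = _jt_normal(groups, observed)
        method = "normal"
    return TrendResult(
        observed, p_inc, p_dec, min(1.0, 2.0 * min(p_inc, p_dec)), method
    )


def decile_trend(
    scores: RecruitmentScores, gene_values: Mapping[str, float], n_bins: int = 10
) -> TrendResult:
    """Bin score-ranked genes into ``n_bins`` near-equal contiguous groups and
    test their values for a monotone trend over the bins.

    Genes are ordered by score rank (rank 1 = strongest attractant first) and
    split so bin sizes differ by at most one; genes without a value are
    skipped. Requires at least 20 genes with values.
    """
    ranked = [g for g in scores.ranked_genes() if g in gene_values]
    if len(ranked) < 20:
        raise ValueError(f"only {len(ranked)} genes with values (< 20)")
    bins = [list(b) for b in np.array_split(np.array(ranked, dtype=object), n_bins)]
    groups = [np.array([gene_values[g] for g in b], dtype=float) for b in bins]
    result = jonckheere_test(groups)
    result.bins = bins
    return result


def peptide_burden(peptide_count, protein_length):
    """Immunogenic-peptide burden: log((count + 1) / protein length)."""
    count = np.asarray(peptide_count, dtype=float)
    length = np.asarray(protein_length, dtype=float)
    if np.any(count < 0) or np.any(length <= 0):
        raise ValueError("counts must be >= 0 and lengths > 0")
    out = np.log((count + 1.0) / length)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rank-sum test with an exact small-sample path
# ---------------------------------------------------------------------------


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration (tie-safe) when both groups have at most 8
    observations, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if max(len(x), len(y)) <= 8:
        pooled = np.concatenate([x, y])
        n1 = len(x)
        ranks = stats.rankdata(pooled)
        mu = n1 * (len(pooled) + 1) / 2.0
        obs = abs(ranks[:n1].sum() - mu)
        count = 0
        total = 0
        for combo in combinations(range(len(pooled)), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def geneset_bag_comparison(
    bags: BagCollection, gene_set: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Gene-set expression in positive vs negative bags.

    Per-bag set score = mean over set genes of the unweighted mean instance
    expression; a two-sided rank-sum test compares the label classes. Returns
    the per-bag score table and the p-value.
    """
    cols = [bags.gene_subset.index(g) for g in gene_set if g in bags.gene_subset]
    if not cols:
        raise ValueError("no gene of the set is in the bag gene subset")
    scores = np.array(
        [bags.expr[np.ix_(b.instance_index, cols)].mean() for b in bags.bags]
    )
    labels = bags.labels
    p = rank_sum_test(scores[labels == 1], scores[labels == 0])
    return pd.DataFrame({"label": labels, "set_score": scores}), p


# ---------------------------------------------------------------------------
# rule classifiers
# ---------------------------------------------------------------------------


def classify_localization(annotations: pd.DataFrame) -> dict[str, str]:
    """Protein localization from compartment annotations.

    Keep only entries with confidence strictly greater than 4. A protein with
    any surviving extracellular entry is extracellular; one whose surviving
    entries are all intracellular is intracellular; a protein with no
    surviving entry is uncertain.

    ``annotations`` columns: protein_id, compartment_class
    (extracellular/intracellular), confidence.
    """
    required = {"protein_id", "compartment_class", "confidence"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    out: dict[str, str] = {str(p): "uncertain" for p in annotations["protein_id"].unique()}
    kept = annotations[annotations["confidence"] > 4]
    for protein, grp in kept.groupby("protein_id"):
        classes = set(grp["compartment_class"])
        out[str(protein)] = "extracellular" if "extracellular" in classes else "intracellular"
    return out


def classify_region(
    ds: SpatialDataset, target_type: str, radius: float = 30.0, threshold: float = 0.5
) -> pd.Series:
    """Per-cell region call from local cell-type composition.

    A cell is in the other (e.g. stromal) region iff the fraction of
    target-type cells among all cells within ``radius`` (the cell itself
    included) is strictly below ``threshold``; otherwise it is in the target
    region.
    """
    target = set(ds.cells_of_type(target_type).tolist())
    tree = cKDTree(ds.coords)
    neighbors = tree.query_ball_point(ds.coords, r=radius)
    calls = []
    for i, local in enumerate(neighbors):
        frac = sum(1 for j in local if j in target) / len(local)
        calls.append("other_region" if frac < threshold else "target_region")
    return pd.Series(calls, index=ds.cell_ids.astype(str), name="region")


def developmental_trend(
    stage_means: Mapping[str, tuple[float, float, float]]
) -> dict[str, str]:
    """Classify genes by their expression trajectory over (fetal, childhood,
    adult) stage means.

    Decreasing: fetal is the strict maximum and adult the strict minimum.
    Increasing: fetal is the strict minimum and adult the strict maximum.
    Anything else is non-directional.
    """
    out = {}
    for gene, (fetal, childhood, adult) in stage_means.items():
        if fetal > childhood and fetal > adult and adult < childhood:
            out[gene] = "decreasing"
        elif fetal < childhood and fetal < adult and adult > childhood:
            out[gene] = "increasing"
        else:
            out[gene] = "non-directional"
    return out
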