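"""Infiltration maps, duality DE, and the rank/overlap/trend statistics."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nichemil as nm
from nichemil.interpret import TrendResult, _jt_statistic

from test_bags import typed_dataset
from test_mil import collection_of, hand_model


class TestPredictRegions:
    def test_negative_bias_predicts_nothing(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 300, size=(200, 2))
        types = np.where(rng.random(200) < 0.15, "engaging", "resident")
        ds = typed_dataset(coords, types, n_genes=3, seed=0)
        model = hand_model(w=[0.0, 0.0, 0.0], gamma=[0.0] * 3, b=-2.0,
                           u=[1.0], a=[0.0], v=[1.0])
        regions = nm.predict_regions(ds, model, radius=50, min_instances=3)
        assert not regions["predicted_infiltrate"].any()
        np.testing.assert_allclose(regions["probability"], 1 / (1 + np.exp(2.0)))

    def test_observed_flags_match_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 400, size=(300, 2))
        types = np.where(rng.random(300) < 0.2, "engaging", "resident")
        ds = typed_dataset(coords, types, n_genes=3, seed=1)
        model = hand_model(w=[0.1, -0.2, 0.3], gamma=[0.0] * 3, b=0.0,
                           u=[1.0], a=[0.0], v=[1.0])
        radius = 40.0
        regions = nm.predict_regions(ds, model, radius=radius, min_instances=3)
        eng_xy = ds.coords[[i for i, t in enumerate(ds.type_labels) if "engaging" in t]]
        for _, row in regions.iterrows():
            center = np.array([row["x_um"], row["y_um"]])
            d = np.linalg.norm(eng_xy - center, axis=1)
            assert row["observed_engaging_within_radius"] == bool((d <= radius).any())

    def test_no_evaluable_points_raises(self):
        ds = typed_dataset([(0, 0), (500, 500)], ["resident", "engaging"], n_genes=2)
        model = hand_model(w=[0.0, 0.0], gamma=[0.0, 0.0], b=0.0,
                           u=[1.0], a=[0.0], v=[1.0])
        with pytest.raises(ValueError, match="evaluable"):
            nm.predict_regions(ds, model, radius=10, min_instances=5)


def region_frame(points, flags):
    return pd.DataFrame(
        {"x_um": [p[0] for p in points], "y_um": [p[1] for p in points],
         "probability": [1.0 if f else 0.0 for f in flags],
         "predicted_infiltrate": flags,
         "observed_engaging_within_radius": flags}
    )


class TestDualityDE:
    def _dataset(self, shift=0.0, n_per_side=40, n_genes=12, seed=0):
        """Engaging cells on the left/right halves; gene 0 shifted on the right."""
        rng = np.random.default_rng(seed)
        n = 2 * n_per_side
        coords = np.vstack([
            rng.uniform([0, 0], [100, 100], size=(n_per_side, 2)),
            rng.uniform([900, 0], [1000, 100], size=(n_per_side, 2)),
        ])
        expr = rng.poisson(5.0, size=(n, n_genes)).astype(float) + 1
        expr[n_per_side:, 0] *= np.exp(shift)
        ds = nm.SpatialDataset(
            cell_ids=np.array([f"e{i}" for i in range(n)], dtype=object),
            coords=coords, expr=expr,
            gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
            type_labels=[{"engaging"}] * n, dataset_id="de",
        )
        return nm.normalize(ds, 100.0)

    def test_identical_groups_null(self):
        ds = self._dataset(shift=0.0, seed=3)
        # evaluated points: one in each half, right half predicted positive
        regions = region_frame([(50, 50), (950, 50)], [False, True])
        table = nm.duality_de(ds, regions, min_cells=10, radius=200.0)
        assert (table["pvalue"] > 0.001).all()
        assert (table["qvalue"] >= table["pvalue"] - 1e-12).all()

    def test_planted_shift_detected(self):
        ds = self._dataset(shift=1.5, n_per_side=200, seed=4)
        regions = region_frame([(50, 50), (950, 50)], [False, True])
        table = nm.duality_de(ds, regions, min_cells=10, radius=200.0)
        top = table.iloc[0]
        assert top["gene"] == "g0"
        assert top["logFC"] == table["logFC"].max() > 0
        assert top["qvalue"] < 0.05

    def test_bh_monotone_in_p(self):
        ds = self._dataset(shift=0.8, n_per_side=60, seed=5)
        regions = region_frame([(50, 50), (950, 50)], [False, True])
        table = nm.duality_de(ds, regions, min_cells=10, radius=200.0).sort_values("pvalue")
        q = table["qvalue"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_empty_class_raises(self):
        ds = self._dataset(seed=6)
        regions = region_frame([(50, 50), (950, 50)], [True, True])
        with pytest.raises(ValueError, match="predicted-negative"):
            nm.duality_de(ds, regions, min_cells=1, radius=200.0)


class TestRankSum:
    def test_exact_matches_brute_force_permutation(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.integers(0, 5, size=6).astype(float)  # ties likely
            y = rng.integers(0, 5, size=7).astype(float)
            got = nm.rank_sum_test(x, y)
            # independent brute force: all assignments of pooled ranks
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mu = len(x) * (len(pooled) + 1) / 2
            obs = abs(ranks[: len(x)].sum() - mu)
            hits, total = 0, 0
            for combo in combinations(range(len(pooled)), len(x)):
                total += 1
                if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
                    hits += 1
            assert got == pytest.approx(hits / total, abs=1e-12)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert nm.rank_sum_test(x, y) == pytest.approx(expected)


def test_signature_score():
    assert nm.signature_score({"a": 1.0, "b": 2.0}, {"a": 0.5, "b": -1.0}) == -1.5
    assert nm.signature_score({"a": 1.0}, {"a": 0.0, "b": 5.0}) == 0.0
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(100)]
    e = dict(zip(genes, rng.normal(size=100)))
    f = dict(zip(genes, rng.normal(size=100)))
    brute = float(np.dot([e[g] for g in genes], [f[g] for g in genes]))
    assert nm.signature_score(e, f) == pytest.approx(brute)
    # linear in both arguments
    e2 = {g: 2 * v for g, v in e.items()}
    assert nm.signature_score(e2, f) == pytest.approx(2 * brute)
    with pytest.raises(ValueError, match="shared"):
        nm.signature_score({"a": 1.0}, {"b": 1.0})


class TestScoreCorrelation:
    def test_self_and_negated(self):
        genes = [f"g{i}" for i in range(15)]
        vals = np.linspace(-1, 1, 15)
        a = nm.RecruitmentScores.from_scores(genes, vals)
        b = nm.RecruitmentScores.from_scores(genes, -vals)
        assert nm.score_correlation(a, a) == pytest.approx(1.0)
        assert nm.score_correlation(a, b) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        genes = [f"g{i}" for i in range(12)]
        va = np.array([1, 1, 2, 3, 3, 3, 4, 5, 5, 6, 7, 7], dtype=float)
        vb = np.array([2, 1, 1, 5, 4, 4, 4, 6, 7, 7, 8, 3], dtype=float)
        a = nm.RecruitmentScores.from_scores(genes, va)
        b = nm.RecruitmentScores.from_scores(genes, vb)
        # average ranks then Pearson, aligned by gene symbol (as in the shared index)
        import pandas as pd
        sa, sb = a.as_series(), b.as_series()
        shared = sorted(set(genes))
        ra = stats.rankdata(sa.loc[shared])
        rb = stats.rankdata(sb.loc[shared])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert nm.score_correlation(a, b) == pytest.approx(expected)

    def test_too_few_shared(self):
        a = nm.RecruitmentScores.from_scores(["a", "b", "c"], [1, 2, 3])
        b = nm.RecruitmentScores.from_scores(["a", "b", "d"], [1, 2, 3])
        with pytest.raises(ValueError, match="shared"):
            nm.score_correlation(a, b)


class TestTopSetOverlap:
    def test_identical_lists_extreme(self):
        genes = [f"g{i}" for i in range(100)]
        out = nm.top_set_overlap({"a": genes, "b": list(genes)}, 0.25)
        row = out.iloc[0]
        assert row["overlap"] == 25 and row["m"] == 25
        expected = float(stats.hypergeom.sf(24, 100, 25, 25))
        assert row["pvalue"] == pytest.approx(expected)
        assert row["pvalue"] < 1e-20

    def test_enumeration_oracle_small(self):
        # N=8, m=4: compare against exhaustive enumeration over all C(8,4)^2 draws
        universe = list("abcdefgh")
        la = ["a", "b", "c", "d", "e", "f", "g", "h"]
        lb = ["a", "b", "e", "c", "h", "g", "f", "d"]
        out = nm.top_set_overlap({"x": la, "y": lb}, 0.5)
        obs = out.iloc[0]["overlap"]
        count = total = 0
        for s1 in combinations(universe, 4):
            for s2 in combinations(universe, 4):
                total += 1
                if len(set(s1) & set(s2)) >= obs:
                    count += 1
        assert out.iloc[0]["pvalue"] == pytest.approx(count / total, abs=1e-12)

    def test_universe_mismatch(self):
        with pytest.raises(ValueError, match="universe"):
            nm.top_set_overlap({"a": ["x", "y"], "b": ["x", "z"]}, 0.5)

    def test_round_half_up(self):
        # N=10, top_fraction=0.25 -> m = round(2.5) = 3 under half-up rounding
        genes = [f"g{i}" for i in range(10)]
        out = nm.top_set_overlap({"a": genes, "b": genes}, 0.25)
        assert out.iloc[0]["m"] == 3


class TestJonckheere:
    def test_perfect_trend(self):
        groups = [np.arange(i * 10, (i + 1) * 10, dtype=float) for i in range(10)]
        res = nm.jonckheere_test(groups)
        assert res.p_increasing < 0.01
        assert res.p_two_sided < 0.02

    def test_constant_data(self):
        res = nm.jonckheere_test([np.ones(5), np.ones(5), np.ones(5)])
        assert res.p_two_sided == 1.0

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(7)
        values = rng.integers(0, 6, size=12).astype(float)
        groups = [values[:4], values[4:8], values[8:]]
        res = nm.jonckheere_test(groups)
        assert res.method == "exact"
        # independent oracle: enumerate every distinct assignment of the 12
        # values to the three group slots via nested combinations
        obs = _jt_statistic(groups)
        ge = total = 0
        idx = set(range(12))
        for g1 in combinations(range(12), 4):
            rest = idx - set(g1)
            for g2 in combinations(sorted(rest), 4):
                g3 = sorted(rest - set(g2))
                jt = _jt_statistic([values[list(g1)], values[list(g2)], values[list(g3)]])
                total += 1
                if jt >= obs - 1e-9:
                    ge += 1
        assert res.p_increasing == pytest.approx(ge / total, abs=1e-12)

    def test_reversal_maps_tails(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.5, 1, size=5) for i in range(3)]
        fwd = nm.jonckheere_test(groups)
        rev = nm.jonckheere_test(groups[::-1])
        # reversing the group order swaps the increasing/decreasing tails
        # (up to the tie mass shared by both inclusive tails)
        assert rev.p_increasing == pytest.approx(fwd.p_decreasing, abs=1e-9)
        assert rev.p_decreasing == pytest.approx(fwd.p_increasing, abs=1e-9)

    def test_normal_approximation_regime(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i * 0.3, 1, size=12) for i in range(10)]
        res = nm.jonckheere_test(groups)
        assert res.method == "normal"
        assert 0 <= res.p_two_sided <= 1


class TestDecileTrend:
    def _scores(self, n=100):
        genes = [f"g{i:03d}" for i in range(n)]
        return nm.RecruitmentScores.from_scores(genes, np.linspace(1, 0, n)), genes

    def test_increasing_values_with_rank(self):
        scores, genes = self._scores(100)
        # values rise along the ranked order -> strong increasing trend
        vals = {g: float(i) for i, g in enumerate(scores.ranked_genes())}
        res = nm.decile_trend(scores, vals)
        assert len(res.bins) == 10
        assert all(abs(len(b) - 10) <= 1 for b in res.bins)
        assert res.p_increasing < 0.01

    def test_constant_values(self):
        scores, genes = self._scores(40)
        res = nm.decile_trend(scores, {g: 1.0 for g in genes})
        assert res.p_two_sided == 1.0

    def test_random_values_non_significant(self):
        scores, genes = self._scores(24)
        rng = np.random.default_rng(1)
        vals = {g: float(v) for g, v in zip(genes, rng.normal(size=24))}
        res = nm.decile_trend(scores, vals, n_bins=3)
        assert 0.0 <= res.p_two_sided <= 1.0
        assert res.p_two_sided > 0.05

    def test_too_few_genes(self):
        scores, genes = self._scores(30)
        with pytest.raises(ValueError, match="< 20"):
            nm.decile_trend(scores, {g: 1.0 for g in genes[:10]})


def test_peptide_burden():
    assert nm.peptide_burden(0, 1) == 0.0
    assert nm.peptide_burden(9, 10) == pytest.approx(0.0)
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=20)
    lengths = rng.integers(100, 2000, size=20)
    np.testing.assert_allclose(
        nm.peptide_burden(counts, lengths), np.log((counts + 1) / lengths)
    )
    with pytest.raises(ValueError):
        nm.peptide_burden(-1, 10)


class TestGenesetBagComparison:
    def test_identical_distribution_null(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 2, size=(4, 5))
        specs = [(x.copy(), rng.uniform(1, 40, 4), lab) for lab in (0, 1) for _ in range(3)]
        bc = collection_of(specs, n_genes=5)
        table, p = nm.geneset_bag_comparison(bc, ["g0", "g2"])
        assert p == pytest.approx(1.0)

    def test_planted_elevation_detected(self):
        rng = np.random.default_rng(5)
        specs = []
        for lab in (0, 1):
            for _ in range(200):
                x = rng.normal(2.0, 0.5, size=(5, 6)).clip(0)
                x[:, :2] += 1.0 * lab  # planted set shift in positive bags
                specs.append((x, rng.uniform(1, 40, 5), lab))
        bc = collection_of(specs, n_genes=6)
        _, p = nm.geneset_bag_comparison(bc, ["g0", "g1"])
        assert p < 0.001

    def test_double_mean_oracle(self):
        rng = np.random.default_rng(6)
        specs = [(rng.uniform(0, 3, size=(rng.integers(2, 6), 4)),
                  rng.uniform(1, 40, 0) if False else None, i % 2) for i in range(8)]
        specs = [(x, rng.uniform(1, 40, len(x)), lab) for x, _, lab in specs]
        bc = collection_of(specs, n_genes=4)
        table, _ = nm.geneset_bag_comparison(bc, ["g1", "g3"])
        for k, b in enumerate(bc.bags):
            brute = np.mean([bc.expr[i, [1, 3]].mean() for i in b.instance_index])
            assert table["set_score"].iloc[k] == pytest.approx(brute)


class TestLocalization:
    def test_confidence_filter_and_precedence(self):
        df = pd.DataFrame(
            {"protein_id": ["P1", "P1", "P2", "P3", "P4", "P4"],
             "compartment_class": ["extracellular", "intracellular", "extracellular",
                                   "intracellular", "extracellular", "intracellular"],
             "confidence": [5, 5, 4, 5, 3, 5]}
        )
        out = nm.classify_localization(df)
        assert out["P1"] == "extracellular"   # any surviving extracellular entry wins
        assert out["P2"] == "uncertain"       # confidence 4 is not > 4
        assert out["P3"] == "intracellular"
        assert out["P4"] == "intracellular"   # extracellular entry filtered out

    def test_brute_force_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            n = 60
            df = pd.DataFrame(
                {"protein_id": [f"P{rng.integers(0, 15)}" for _ in range(n)],
                 "compartment_class": rng.choice(["extracellular", "intracellular"], n),
                 "confidence": rng.integers(1, 8, n)}
            )
            got = nm.classify_localization(df)
            for protein in df["protein_id"].unique():
                rows = df[(df["protein_id"] == protein) & (df["confidence"] > 4)]
                if len(rows) == 0:
                    expected = "uncertain"
                elif (rows["compartment_class"] == "extracellular").any():
                    expected = "extracellular"
                else:
                    expected = "intracellular"
                assert got[str(protein)] == expected


class TestClassifyRegion:
    def test_minority_fraction_is_other_region(self):
        # center cell plus 5 neighbors within 30 um, 2 of 6 are tumor
        coords = [(0, 0)] + [(10 * np.cos(t), 10 * np.sin(t))
                             for t in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
        types = ["tumor", "tumor", "stroma", "stroma", "stroma", "stroma"]
        ds = typed_dataset(coords, types, n_genes=2)
        calls = nm.classify_region(ds, "tumor", radius=30.0, threshold=0.5)
        assert (calls == "other_region").all()

    def test_isolated_target_cell(self):
        ds = typed_dataset([(0, 0), (500, 500)], ["tumor", "stroma"], n_genes=2)
        calls = nm.classify_region(ds, "tumor", radius=30.0, threshold=0.5)
        assert calls.iloc[0] == "target_region"  # fraction 1 (only itself)
        assert calls.iloc[1] == "other_region"

    def test_exhaustive_scan_oracle_and_rigid_motion(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 300, size=(300, 2))
        types = np.where(rng.random(300) < 0.5, "tumor", "stroma")
        ds = typed_dataset(coords, types, n_genes=2)
        calls = nm.classify_region(ds, "tumor", radius=30.0, threshold=0.5)
        tumor = types == "tumor"
        for i in range(300):
            d = np.linalg.norm(coords - coords[i], axis=1)
            inside = d <= 30.0
            frac = tumor[inside].mean()
            expected = "other_region" if frac < 0.5 else "target_region"
            assert calls.iloc[i] == expected
        theta = 1.2
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = typed_dataset(coords @ R.T + [77, -13], types, n_genes=2)
        calls2 = nm.classify_region(moved, "tumor", radius=30.0, threshold=0.5)
        assert (calls.to_numpy() == calls2.to_numpy()).all()


class TestDevelopmentalTrend:
    def test_examples(self):
        out = nm.developmental_trend({"a": (3, 2, 1), "b": (1, 3, 2)})
        assert out["a"] == "decreasing"
        assert out["b"] == "non-directional"

    def test_all_orderings(self):
        for perm in permutations([1.0, 2.0, 3.0]):
            fetal, childhood, adult = perm
            got = nm.developmental_trend({"g": perm})["g"]
            if fetal == 3.0 and adult == 1.0:
                assert got == "decreasing"
            elif fetal == 1.0 and adult == 3.0:
                assert got == "increasing"
            else:
                assert got == "non-directional"
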