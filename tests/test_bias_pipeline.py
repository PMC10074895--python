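import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tests.conftest import make_triads
from triadbias.bias_pipeline import (
    BiasSummary,
    PipelineError,
    audit_denominators,
    balanced_breakdown,
    calls_to_frame,
    category_proportions,
    classify_groups,
    marker_bias_summary,
    pseudobulk_means,
    ratio_table,
    suppressed_dominant_ratio,
    unbalanced_fraction,
)
from triadbias.io import CountMatrix
from triadbias.triad_core import NOT_EXPRESSED, BiasCall, TriadComposition


def cm_from_dense(arr, genes=None, barcodes=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(arr.shape[1])]
    return CountMatrix(sp.csr_matrix(arr), genes, barcodes)


def annotate(barcodes, clusters):
    return pd.DataFrame({"cell_id": barcodes, "cluster": clusters})


def call(tid, category, comp=None, distance=0.0):
    if category == NOT_EXPRESSED:
        return BiasCall(tid, category, float("nan"), None)
    comp = comp or TriadComposition(1 / 3, 1 / 3, 1 / 3)
    return BiasCall(tid, category, distance, comp)


class TestPseudobulkMeans:
    def test_raw_mean_arithmetic(self):
        cm = cm_from_dense([[2, 4]])
        expr = pseudobulk_means(cm, annotate(cm.barcodes, ["x", "x"]), "raw_mean")
        assert expr.loc["g0", "x"] == pytest.approx(3.0)

    def test_one_cell_per_group_is_identity(self):
        cm = cm_from_dense([[5, 1], [5, 9]])
        expr = pseudobulk_means(cm, annotate(cm.barcodes, ["u", "v"]), "raw_mean")
        assert expr["u"].tolist() == [5, 5]
        assert expr["v"].tolist() == [1, 9]

    def test_cp10k_matches_brute_force(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(3.0, size=(20, 15))
        clusters = rng.choice(["a", "b", "c"], size=15).tolist()
        cm = cm_from_dense(arr)
        expr = pseudobulk_means(cm, annotate(cm.barcodes, clusters), "cp10k")
        # independent recomputation: scale each cell to 1e4, average per group
        scaled = arr / arr.sum(axis=0, keepdims=True) * 1e4
        for g in set(clusters):
            idx = [i for i, c in enumerate(clusters) if c == g]
            expected = scaled[:, idx].mean(axis=1)
            assert expr[g].to_numpy() == pytest.approx(expected)

    def test_column_order_is_first_appearance(self):
        cm = cm_from_dense(np.ones((2, 4)))
        expr = pseudobulk_means(cm, annotate(cm.barcodes, ["z", "a", "z", "m"]), "raw_mean")
        assert list(expr.columns) == ["z", "a", "m"]

    def test_missing_annotation_errors_with_ids(self):
        cm = cm_from_dense(np.ones((2, 2)))
        ann = annotate(["c0"], ["x"])
        with pytest.raises(PipelineError, match="c1"):
            pseudobulk_means(cm, ann)

    def test_zero_count_cell_stays_zero_in_cp10k(self):
        cm = cm_from_dense([[0, 2], [0, 2]])
        expr = pseudobulk_means(cm, annotate(cm.barcodes, ["x", "x"]), "cp10k")
        assert np.isfinite(expr["x"]).all()

    def test_pooling_consistency_raw_mean(self, small_dataset):
        _, cm, ann, _, _ = small_dataset
        per_cluster = pseudobulk_means(cm, ann, "raw_mean")
        pooled = pseudobulk_means(cm, ann.assign(cluster="all"), "raw_mean")
        sizes = ann["cluster"].value_counts()
        weighted = sum(
            per_cluster[g] * sizes[g] for g in per_cluster.columns
        ) / sizes.sum()
        assert pooled["all"].to_numpy() == pytest.approx(weighted.to_numpy())


class TestClassifyGroups:
    def test_all_zero_group_not_expressed(self):
        triads = make_triads(2)
        expr = pd.DataFrame({"dead": [0.0] * 6}, index=triads.genes)
        calls = classify_groups(expr, triads)
        assert all(c.category == NOT_EXPRESSED for c in calls["dead"])

    def test_matches_per_group_oracle(self, small_dataset, oracle, centroid_matrix):
        _, cm, ann, triads, _ = small_dataset
        expr = pseudobulk_means(cm, ann)
        calls = classify_groups(expr, triads, min_total_expr=0.5)
        table = triads.data
        for group in expr.columns:
            col = expr[group]
            for c, row in zip(calls[group], table.itertuples()):
                vals = np.array([col[row.gene_a], col[row.gene_b], col[row.gene_d]])
                if vals.sum() <= 0.5:
                    assert c.category == NOT_EXPRESSED
                else:
                    cat, dist = oracle(vals / vals.sum(), centroid_matrix)
                    assert c.category == cat
                    assert c.distance == pytest.approx(dist)


class TestCategoryProportions:
    def test_counting(self):
        calls = {
            "g": [call(f"t{i}", c) for i, c in enumerate(
                ["Balance"] * 6 + ["A.dominant"] * 2 + ["A.suppressed"] * 2
            )]
        }
        summary = category_proportions(calls)
        props = summary.table.set_index("category")["proportion"]
        assert props["Balance"] == pytest.approx(0.6)
        assert props["A.dominant"] == pytest.approx(0.2)
        assert props["A.suppressed"] == pytest.approx(0.2)
        assert props["B.dominant"] == 0.0

    def test_empty_expressed_set_gives_nan(self):
        calls = {"g": [call("t1", NOT_EXPRESSED)]}
        summary = category_proportions(calls)
        sub = summary.table[summary.table["category"] != NOT_EXPRESSED]
        assert sub["proportion"].isna().all()
        assert sub["count"].eq(0).all()

    def test_proportions_sum_to_one(self, small_dataset):
        _, cm, ann, triads, _ = small_dataset
        expr = pseudobulk_means(cm, ann)
        summary = category_proportions(classify_groups(expr, triads))
        sub = summary.table[summary.table["category"] != NOT_EXPRESSED]
        assert sub.groupby("group")["proportion"].sum().to_numpy() == pytest.approx(
            np.ones(expr.shape[1])
        )

    def test_sampling_matches_planted_probs(self):
        from triadbias.synthetic import SimulationConfig, plant_truth

        probs = (0.4, 0.08, 0.08, 0.08, 0.12, 0.12, 0.12)
        config = SimulationConfig(
            n_triads=2000, n_clusters=1, cells_per_cluster=5,
            category_probs=probs, seed=17,
        )
        truth = plant_truth(config)
        observed = truth["category"].value_counts(normalize=True)
        from triadbias.triad_core import CATEGORIES

        for cat, p in zip(CATEGORIES, probs):
            # ~4 sigma multinomial tolerance at n=2000
            tol = 4 * np.sqrt(p * (1 - p) / 2000)
            assert observed.get(cat, 0.0) == pytest.approx(p, abs=tol)

    def test_denominator_discipline(self, small_dataset):
        _, cm, ann, triads, _ = small_dataset
        expr = pseudobulk_means(cm, ann)
        summary = category_proportions(classify_groups(expr, triads))
        audit_denominators(summary, len(triads))


class TestSuppressedDominantRatio:
    def _summary(self, a_supp, a_dom):
        calls = {
            "g": [call(f"s{i}", "A.suppressed") for i in range(a_supp)]
            + [call(f"d{i}", "A.dominant") for i in range(a_dom)]
        }
        return category_proportions(calls)

    def test_ratio(self):
        assert suppressed_dominant_ratio(self._summary(18, 10), "A", "g") == pytest.approx(1.8)

    def test_equal_counts(self):
        assert suppressed_dominant_ratio(self._summary(4, 4), "A", "g") == pytest.approx(1.0)

    def test_zero_dominant_warns_inf(self):
        with pytest.warns(RuntimeWarning):
            r = suppressed_dominant_ratio(self._summary(3, 0), "A", "g")
        assert np.isinf(r)

    def test_bad_subgenome(self):
        with pytest.raises(ValueError):
            suppressed_dominant_ratio(self._summary(1, 1), "Z", "g")

    def test_planted_two_to_one_ratio(self):
        from triadbias.synthetic import SimulationConfig, plant_truth

        # A.suppressed twice as likely as A.dominant
        probs = (0.4, 0.1, 0.05, 0.05, 0.2, 0.1, 0.1)
        config = SimulationConfig(
            n_triads=3000, n_clusters=1, cells_per_cluster=5,
            category_probs=probs, seed=1,
        )
        truth = plant_truth(config)
        counts = truth["category"].value_counts()
        ratio = counts["A.suppressed"] / counts["A.dominant"]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_ratio_table_covers_all(self):
        table = ratio_table(self._summary(2, 1))
        assert len(table) == 3
        assert set(table["subgenome"]) == {"A", "B", "D"}


class TestBalancedBreakdown:
    def test_identical_calls_fraction_zero(self):
        bulk = [call("t1", "Balance"), call("t2", "A.dominant")]
        clusters = {"c1": list(bulk)}
        bd = balanced_breakdown(bulk, clusters)
        assert unbalanced_fraction(bd)["c1"] == pytest.approx(0.0)

    def test_counting_example(self):
        bulk = [call(f"t{i}", "Balance") for i in range(4)]
        clusters = {
            "c1": [
                call("t0", "Balance"),
                call("t1", "Balance"),
                call("t2", "A.dominant"),
                call("t3", "D.suppressed"),
            ]
        }
        bd = balanced_breakdown(bulk, clusters)
        assert unbalanced_fraction(bd)["c1"] == pytest.approx(0.5)

    def test_not_expressed_excluded_from_denominator(self):
        bulk = [call(f"t{i}", "Balance") for i in range(3)]
        clusters = {
            "c1": [call("t0", "Balance"), call("t1", "A.dominant"), call("t2", NOT_EXPRESSED)]
        }
        bd = balanced_breakdown(bulk, clusters)
        assert unbalanced_fraction(bd)["c1"] == pytest.approx(0.5)
        bal = bd[(bd["group"] == "c1") & (bd["category"] == "Balance")].iloc[0]
        assert bal["proportion_all"] == pytest.approx(1 / 3)

    def test_disjoint_triad_sets_error(self):
        bulk = [call("t1", "Balance")]
        clusters = {"c1": [call("other", "Balance")]}
        with pytest.raises(PipelineError):
            balanced_breakdown(bulk, clusters)

    def test_opposing_dominance_phenomenon(self):
        # A-dominant in one cluster mirrored by A-suppressed in the other:
        # pooled pseudobulk calls Balance, clusters call non-Balance
        from triadbias.synthetic import SimulationConfig, plant_truth, simulate_counts

        config = SimulationConfig(
            n_triads=200,
            n_clusters=2,
            cells_per_cluster=150,
            category_probs=[
                (0, 1, 0, 0, 0, 0, 0),  # all A.dominant
                (0, 0, 0, 0, 1, 0, 0),  # all A.suppressed
            ],
            dirichlet_concentration=1e4,
            dropout_rate=0.1,
            mean_total_expr=20.0,
            seed=31,
        )
        cm, ann, triads = simulate_counts(plant_truth(config), config)
        cluster_expr = pseudobulk_means(cm, ann, "raw_mean")
        bulk_expr = pseudobulk_means(cm, ann.assign(cluster="bulk"), "raw_mean")
        cluster_calls = classify_groups(cluster_expr, triads)
        bulk_calls = classify_groups(bulk_expr, triads)["bulk"]
        n_bal = sum(1 for c in bulk_calls if c.category == "Balance")
        assert n_bal / len(bulk_calls) > 0.9
        frac = unbalanced_fraction(balanced_breakdown(bulk_calls, cluster_calls))
        assert (frac > 0.9).all()


class TestMarkerBiasSummary:
    def _setup(self):
        triads = make_triads(3)
        calls = {
            "c1": [call("t0", "Balance"), call("t1", "A.dominant"), call("t2", "Balance")]
        }
        return triads, calls

    def test_only_balanced_markers(self):
        triads, calls = self._setup()
        table = marker_bias_summary(calls, {"c1": ["a0", "b2"]}, triads)
        assert table.iloc[0]["fraction_unbalanced"] == pytest.approx(0.0)

    def test_half_unbalanced(self):
        triads, calls = self._setup()
        table = marker_bias_summary(calls, {"c1": ["a0", "a1"]}, triads)
        row = table.iloc[0]
        assert row["n_marker_triads"] == 2
        assert row["fraction_unbalanced"] == pytest.approx(0.5)

    def test_unmapped_markers_counted(self):
        triads, calls = self._setup()
        table = marker_bias_summary(calls, {"c1": ["a0", "zzz"]}, triads)
        assert table.iloc[0]["n_markers_unmapped"] == 1

    def test_empty_marker_set_gives_nan(self):
        triads, calls = self._setup()
        table = marker_bias_summary(calls, {"c1": []}, triads)
        assert np.isnan(table.iloc[0]["fraction_unbalanced"])

    def test_planted_marker_bias_recovery(self):
        # markers planted non-Balance with probability 0.6
        rng = np.random.default_rng(5)
        n = 500
        triads = make_triads(n)
        cats = np.where(rng.random(n) < 0.6, "A.dominant", "Balance")
        calls = {"c1": [call(f"t{i}", c) for i, c in enumerate(cats)]}
        markers = {"c1": [f"a{i}" for i in range(n)]}
        table = marker_bias_summary(calls, markers, triads)
        assert table.iloc[0]["fraction_unbalanced"] == pytest.approx(0.6, abs=0.06)


class TestCallsToFrame:
    def test_long_format_roundtrip_values(self):
        calls = {"g": [call("t1", "Balance"), call("t2", NOT_EXPRESSED)]}
        frame = calls_to_frame(calls)
        assert list(frame.columns) == [
            "triad_id", "group", "fa", "fb", "fd", "category", "distance",
        ]
        assert frame.loc[frame["triad_id"] == "t2", "fa"].isna().all()
        assert len(frame) == 2
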