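"""Cohort statistics: DE, median split, KM/log-rank, chi-square, correlation,
hierarchical clustering — each against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsrnakit import cohort as coh
from tsrnakit.quantify import ExpressionMatrix
from tsrnakit.simulate import SimulationConfig, simulate_cohort


def _annotation(n_a, n_b):
    samples = [f"T{i}" for i in range(n_a)] + [f"N{i}" for i in range(n_b)]
    return pd.DataFrame(
        {"group": ["tumor"] * n_a + ["nontumor"] * n_b},
        index=pd.Index(samples, name="sample_id"),
    )


class TestDifferentialExpression:
    def test_identical_groups_give_t0_p1(self):
        ann = _annotation(3, 3)
        data = pd.DataFrame([[4, 5, 6, 4, 5, 6]], index=["f1"], columns=ann.index,
                            dtype=float)
        res = coh.differential_expression(data, ann)
        assert res.loc["f1", "statistic"] == pytest.approx(0.0)
        assert res.loc["f1", "p_value"] == pytest.approx(1.0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(8)
        ann = _annotation(10, 8)
        data = pd.DataFrame(rng.exponential(50, size=(20, 18)),
                            index=[f"f{i}" for i in range(20)], columns=ann.index)
        res = coh.differential_expression(data, ann)
        logd = np.log2(data + 1)
        for fid in data.index:
            t, p = stats.ttest_ind(logd.loc[fid, ann.index[:10]],
                                   logd.loc[fid, ann.index[10:]], equal_var=False)
            assert res.loc[fid, "statistic"] == pytest.approx(t)
            assert res.loc[fid, "p_value"] == pytest.approx(p)

    def test_planted_downregulation_recovered(self):
        cfg = SimulationConfig(seed=42, n_tumor=30, n_nontumor=30,
                               planted_log2fc=-1.0, n_planted=2)
        sim = simulate_cohort([f"f{i}" for i in range(100)], cfg)
        counts = sim["counts"]
        rpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
        res = coh.differential_expression(rpm, sim["annotation"])
        for fid in sim["truth"]["planted_fragments"]:
            assert res.loc[fid, "effect"] < 0
            assert res.loc[fid, "q_value"] < 0.05

    def test_degenerate_two_sample_group_flagged(self):
        ann = _annotation(2, 2)
        data = pd.DataFrame([[3.0, 3.0, 5.0, 6.0]], index=["f1"], columns=ann.index)
        res = coh.differential_expression(data, ann)
        assert bool(res.loc["f1", "degenerate"])
        assert np.isfinite(res.loc["f1", "p_value"])

    def test_too_few_samples_rejected(self):
        ann = _annotation(1, 3)
        data = pd.DataFrame([[1.0, 2, 3, 4]], index=["f1"], columns=ann.index)
        with pytest.raises(ValueError, match="2 samples"):
            coh.differential_expression(data, ann)

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        ann = _annotation(5, 5)
        data = pd.DataFrame(rng.exponential(20, size=(40, 10)),
                            index=[f"f{i}" for i in range(40)], columns=ann.index)
        res = coh.differential_expression(data, ann).sort_values("p_value")
        assert (res["q_value"].to_numpy()[1:] >= res["q_value"].to_numpy()[:-1] - 1e-12).all()
        assert (res["q_value"] <= 1).all()
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values,low,high",
        [
            ([1, 2, 3, 4], ["s0", "s1"], ["s2", "s3"]),
            ([1, 2, 2, 4], ["s0", "s1", "s2"], ["s3"]),  # ties to low
            ([1, 2, 3], ["s0", "s1"], ["s2"]),  # odd n
        ],
    )
    def test_split_rules(self, values, low, high):
        s = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        labels = coh.median_split(s)
        assert list(labels.index[labels == "low"]) == low
        assert list(labels.index[labels == "high"]) == high

    def test_constant_values_warn_all_low(self):
        with pytest.warns(UserWarning, match="low"):
            labels = coh.median_split(pd.Series([5.0, 5.0, 5.0]))
        assert (labels == "low").all()


def _lifelines_logrank(times, events, groups):
    from lifelines.statistics import logrank_test as ll

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    res = ll(t[g == labels[0]], t[g == labels[1]],
             event_observed_A=e[g == labels[0]], event_observed_B=e[g == labels[1]])
    return res.test_statistic, res.p_value


class TestKMLogrank:
    def test_km_curve_shape(self):
        curve = coh.km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        assert curve["survival"].iloc[0] <= 1.0
        s = curve["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()  # non-increasing
        assert curve["at_risk"].iloc[0] == 4

    def test_fully_censored_group_stays_at_one(self):
        curve = coh.km_estimate([5, 6, 7], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a"] * 3 + ["b"] * 3
        stat, p = coh.logrank_test(t, e, g)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_four_sample_case_matches_oracle(self):
        # group A dies at 1,2; group B at 3,4 — textbook hand case
        t, e, g = [1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"]
        stat, p = coh.logrank_test(t, e, g)
        o_stat, o_p = _lifelines_logrank(t, e, g)
        assert stat == pytest.approx(o_stat, abs=1e-9)
        assert p == pytest.approx(o_p, abs=1e-9)

    def test_exhaustive_small_cases_match_lifelines(self):
        # every event pattern and balanced-ish group assignment for n=5,
        # with tied death times included
        times = [1, 2, 2, 3, 4]
        count = 0
        for events in itertools.product([0, 1], repeat=5):
            if sum(events) == 0:
                continue
            for mask in itertools.combinations(range(5), 2):
                groups = ["b"] * 5
                for i in mask:
                    groups[i] = "a"
                stat, p = coh.logrank_test(times, list(events), groups)
                if np.isnan(stat):
                    continue  # degenerate: no between-group information
                o_stat, o_p = _lifelines_logrank(times, list(events), groups)
                assert stat == pytest.approx(o_stat, abs=1e-9)
                assert p == pytest.approx(o_p, abs=1e-9)
                count += 1
        assert count > 200

    def test_statistic_invariant_under_label_swap(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(100, 30)
        e = rng.integers(0, 2, 30)
        g = np.where(rng.random(30) < 0.5, "low", "high")
        if e.sum() == 0:
            e[0] = 1
        s1, _ = coh.logrank_test(t, e, g)
        s2, _ = coh.logrank_test(t, e, np.where(g == "low", "high", "low"))
        assert s1 == pytest.approx(s2)

    def test_no_events_reports_na(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = coh.logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert np.isnan(stat) and np.isnan(p)

    def test_km_logrank_bundles_curves_per_group(self):
        res = coh.km_logrank([1, 2, 3, 4], [1, 1, 0, 0], ["a", "a", "b", "b"])
        assert set(res["curves"]) == {"a", "b"}
        assert (res["curves"]["b"]["survival"] == 1.0).all()


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = coh.chisq_association(["low"] * 20 + ["high"] * 20,
                                    ["x"] * 10 + ["y"] * 10 + ["x"] * 10 + ["y"] * 10)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_20_5_table_statistic_exact(self):
        expr = ["low"] * 25 + ["high"] * 25
        feat = ["m"] * 20 + ["w"] * 5 + ["m"] * 5 + ["w"] * 20
        res = coh.chisq_association(expr, feat)
        # all expected counts 12.5; chi2 = 4 * 7.5^2 / 12.5 = 18 exactly
        assert res["statistic"] == pytest.approx(18.0, abs=1e-12)
        assert res["df"] == 1

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(4)
        expr = rng.choice(["low", "high"], 60)
        feat = rng.choice(["a", "b", "c"], 60)
        r1 = coh.chisq_association(expr, feat)
        relabel = {"a": "c", "b": "a", "c": "b"}
        r2 = coh.chisq_association(expr, [relabel[f] for f in feat])
        assert r1["statistic"] == pytest.approx(r2["statistic"])
        assert r1["df"] == r2["df"] == 2

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            coh.chisq_association(["low"] * 10, ["a"] * 5 + ["b"] * 5)


class TestCorrelation:
    def test_linear_relation_pearson_one(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        mrna = pd.DataFrame([2 * x + 3], index=["g1"])
        res = coh.correlate_with_mrna(x, mrna, "pearson")
        assert res.loc["g1", "effect"] == pytest.approx(1.0)

    def test_monotone_invariance_of_spearman(self):
        x = pd.Series([0.1, 0.5, 1.0, 2.0, 3.0], index=list("abcde"))
        mrna = pd.DataFrame([np.exp(x)], index=["g1"])
        sp = coh.correlate_with_mrna(x, mrna, "spearman")
        pe = coh.correlate_with_mrna(x, mrna, "pearson")
        assert sp.loc["g1", "effect"] == pytest.approx(1.0)
        assert pe.loc["g1", "effect"] < 1.0

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(12)
        n = 100
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        rho = 0.6
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        mrna = pd.DataFrame([y, rng.normal(size=n)], index=["planted", "null"],
                            columns=x.index)
        res = coh.correlate_with_mrna(x, mrna, "pearson")
        assert res.loc["planted", "effect"] == pytest.approx(rho, abs=0.15)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        mrna = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=[f"g{i}" for i in range(5)], columns=x.index)
        res = coh.correlate_with_mrna(x, mrna, "pearson")
        for g in mrna.index:
            r, p = stats.pearsonr(x, mrna.loc[g])
            assert res.loc[g, "effect"] == pytest.approx(r)
            assert res.loc[g, "p_value"] == pytest.approx(p, rel=1e-6)

    def test_constant_gene_flagged_nan(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        mrna = pd.DataFrame([[7.0, 7, 7, 7]], index=["flat"], columns=x.index)
        res = coh.correlate_with_mrna(x, mrna)
        assert np.isnan(res.loc["flat", "effect"])
        assert res.loc["flat", "flag"] == "constant"


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"], dtype=float)
        res = coh.hierarchical_cluster(df)
        i, j, h, size = res["merges"][0]
        assert {i, j} == {0, 1}  # perfectly correlated pair merges first
        assert h == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(23)
        for _ in range(5):
            data = rng.normal(size=(8, 6))
            df = pd.DataFrame(data, index=[f"r{i}" for i in range(8)])
            res = coh.hierarchical_cluster(df)
            d = 1 - np.corrcoef(data)
            np.fill_diagonal(d, 0)
            d = (d + d.T) / 2
            z = linkage(squareform(d, checks=False), method="average")
            ours = sorted(h for _, _, h, _ in res["merges"])
            theirs = sorted(z[:, 2])
            assert np.allclose(ours, theirs, atol=1e-9)

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"r{i}" for i in range(6)])
        res = coh.hierarchical_cluster(df)
        assert sorted(res["leaf_order"]) == sorted(df.index)

    def test_zero_variance_row_at_distance_one(self):
        df = pd.DataFrame([[1.0, 1, 1], [1, 2, 3], [3, 2, 1]], index=list("abc"))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = coh.hierarchical_cluster(df)
        assert len(res["merges"]) == 2


def test_annotation_loader_validates(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("sample_id\tgroup\tsurvival_time\tevent\ns1\ttumor\t-5\t1\n")
    with pytest.raises(ValueError, match="negative"):
        coh.load_cohort_annotation(p)
    p.write_text("sample_id\tgroup\tsurvival_time\tevent\ns1\ttumor\t100\t1\n")
    ann = coh.load_cohort_annotation(p)
    assert ann.loc["s1", "group"] == "tumor"
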