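"""Inferential layer: paired t, clustered correlations, ICC, Spearman,
AUROC, DeLong, group means and cohort filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from npabench.stats import (
    DegenerateDataError,
    auroc,
    cluster_bootstrap,
    delong_test,
    first_scan_filter,
    group_means,
    icc_agreement,
    paired_t,
    pearson_clustered,
    pearson_diff,
    spearman_diff,
    spearman_rho,
)


class TestPairedT:
    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t(np.array([1.0, 1.0, 1.0, 1.0]))

    def test_symmetric_pair(self):
        res = paired_t(np.array([-1.0, 1.0]))
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 10)
            res = paired_t(d)
            ref = sps.ttest_1samp(d, 0.0)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.estimate == pytest.approx(d.mean())


class TestPearsonClustered:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_clustered(x, 2 * x + 1, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_clustered(np.ones(5), np.arange(5.0), n_boot=200)

    def test_singleton_clusters_equal_case_resampling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        a = pearson_clustered(x, y, None, n_boot=500, seed=7)
        b = pearson_clustered(x, y, np.arange(40), n_boot=500, seed=7)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_diff_of_identical_methods_is_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson_diff(x, x, y, n_boot=500, seed=0)
        assert res.estimate == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high


class TestICC:
    def test_identity(self):
        x = np.arange(10.0)
        res = icc_agreement(x, x, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(1.0)

    def test_offset_penalized_vs_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x + 3.0
        icc = icc_agreement(x, y, n_boot=200, seed=0).estimate
        r = np.corrcoef(x, y)[0, 1]
        assert icc < r

    def test_matches_variance_components_oracle(self):
        # independent two-way absolute-agreement computation via pingouin
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            x = rng.normal(size=n)
            y = 0.8 * x + rng.normal(0, 0.4, n) + 0.2
            df = pd.DataFrame(
                {
                    "t": np.r_[np.arange(n), np.arange(n)],
                    "r": ["A"] * n + ["B"] * n,
                    "v": np.r_[x, y],
                }
            )
            table = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
            ref = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            est = icc_agreement(x, y, n_boot=100, seed=0).estimate
            assert est == pytest.approx(ref, abs=1e-8)

    def test_equal_moments_icc_equals_pearson(self):
        # constructed sample where both methods share mean and variance
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        y = np.roll(x, 1) * 0.5 + x * 0.5
        y = (y - y.mean()) / y.std() * x.std() + x.mean()
        icc = icc_agreement(x, y, n_boot=100, seed=0).estimate
        r = np.corrcoef(x, y)[0, 1]
        assert icc == pytest.approx(r, abs=1e-2)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.5, 1.2, 3.0, 7.7, 9.1])
        assert spearman_rho(x, np.exp(x)).estimate == pytest.approx(1.0)

    def test_midranks_match_hand_ranked_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 2.0, 2.0])
        # ranks of y with midranks: (1.5, 1.5, 3.5, 3.5); Pearson of ranks
        ref = np.corrcoef([1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5])[0, 1]
        assert spearman_rho(x, y).estimate == pytest.approx(ref)

    def test_all_tied_outcome_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho(np.arange(5.0), np.ones(5))

    def test_identical_methods_zero_difference(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = (x > 0).astype(float) + (x > 1)
        res = spearman_diff(x, x, y, n_boot=500, seed=0)
        assert res.estimate == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high


class TestAUROC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert auroc(scores, labels, n_boot=200, seed=0).estimate == 1.0

    def test_all_tied_scores_half(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert auroc(np.ones(10), labels, n_boot=200, seed=0).estimate == 0.5

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(6, 60))
            scores = rng.integers(0, 8, n).astype(float)  # force ties
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            pos = scores[labels][:, None]
            neg = scores[~labels][None, :]
            brute = ((pos > neg) + 0.5 * (pos == neg)).mean()
            res = auroc(scores, labels, n_boot=100, seed=0)
            assert res.estimate == brute

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = rng.uniform(size=50) < 0.5
        labels[0] = True
        labels[1] = False
        res = auroc(scores, labels, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(roc_auc_score(labels, scores))

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            auroc(np.arange(5.0), np.ones(5, bool), n_boot=100)


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=30)
        labels = rng.uniform(size=30) < 0.5
        labels[0], labels[1] = True, False
        res = delong_test(s, s, labels)
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        labels = rng.uniform(size=40) < 0.5
        labels[0], labels[1] = True, False
        base = rng.normal(size=40) + labels
        sA = base + rng.normal(0, 0.5, 40)
        sB = base + rng.normal(0, 0.8, 40)
        ab = delong_test(sA, sB, labels)
        ba = delong_test(sB, sA, labels)
        assert ab.estimate == pytest.approx(-ba.estimate)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            delong_test(np.arange(4.0), np.arange(4.0), np.ones(4, bool))


class TestGroupMeans:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(10.0), 2)
        groups = np.r_[["a"] * 10, ["b"] * 10]
        cid = np.tile(np.arange(10), 2)
        out = group_means(vals, groups, cid, n_boot=500, seed=0)
        row = out[out["group"] == "b"].iloc[0]
        assert row["diff_vs_ref"] == 0.0
        assert row["p_value"] > 0.5

    def test_shift_recovery(self):
        rng = np.random.default_rng(12)
        delta = 0.7
        a = rng.normal(0, 1, 200)
        b = rng.normal(delta, 1, 200)
        vals = np.r_[a, b]
        groups = np.r_[["a"] * 200, ["b"] * 200]
        cid = np.arange(400)
        out = group_means(vals, groups, cid, n_boot=500, seed=0)
        row = out[out["group"] == "b"].iloc[0]
        assert row["diff_vs_ref"] == pytest.approx(b.mean() - a.mean())
        assert abs(row["diff_vs_ref"] - delta) < 0.25

    def test_ci_width_shrinks_with_clusters(self):
        rng = np.random.default_rng(13)
        widths = []
        for m in (25, 100, 400):
            a = rng.normal(0, 1, m)
            b = rng.normal(0.5, 1, m)
            vals = np.r_[a, b]
            groups = np.r_[["a"] * m, ["b"] * m]
            cid = np.arange(2 * m)
            out = group_means(vals, groups, cid, n_boot=800, seed=0)
            row = out[out["group"] == "b"].iloc[0]
            widths.append(row["ci_high"] - row["ci_low"])
        assert widths[0] > widths[1] > widths[2]
        # ~1/sqrt(m) scaling across a 16x span of cluster counts
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            group_means(
                np.arange(4.0), np.array(["a"] * 4), np.arange(4), n_boot=100,
                group_order=["a", "b"],
            )


class TestFirstScanFilter:
    def table(self):
        return pd.DataFrame(
            {
                "eye_id": ["e1"] * 3 + ["e2"] * 2,
                "slab": ["SVC"] * 5,
                "visit_index": [1, 2, 3, 1, 2],
                "ssi": [70.0, 80.0, 90.0, 54.9, 55.0],
            }
        )

    def test_first_visit_kept(self):
        out = first_scan_filter(self.table())
        assert out[out["eye_id"] == "e1"]["visit_index"].tolist() == [1]

    def test_ssi_cutoff_inclusive_boundary(self):
        out = first_scan_filter(self.table())
        e2 = out[out["eye_id"] == "e2"]
        # 54.9 excluded, 55.0 retained (cutoff defines exclusion as < 55)
        assert e2["ssi"].tolist() == [55.0]

    def test_identity_on_clean_table(self):
        t = pd.DataFrame(
            {
                "eye_id": ["e1", "e2"],
                "slab": ["SVC", "SVC"],
                "visit_index": [1, 1],
                "ssi": [70.0, 60.0],
            }
        )
        out = first_scan_filter(t)
        assert out[["eye_id", "visit_index", "ssi"]].equals(
            t[["eye_id", "visit_index", "ssi"]]
        )


def test_cluster_bootstrap_reproducible_and_cluster_based():
    rng_a = np.random.default_rng(5)
    rng_b = np.random.default_rng(5)
    x = np.arange(12.0)
    cid = np.repeat(np.arange(4), 3)
    fn = lambda idx: x[idx].mean()
    a = cluster_bootstrap(fn, 12, cid, 100, rng_a)
    b = cluster_bootstrap(fn, 12, cid, 100, rng_b)
    assert np.array_equal(a, b)
    # with strong cluster structure, cluster draws are coarser than iid draws
    assert len(np.unique(np.round(a, 6))) <= 100
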