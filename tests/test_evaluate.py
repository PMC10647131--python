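"""Confusion metrics, ROC/PRC areas, DeLong tests, signature harness."""

import math

import numpy as np
import pandas as pd
import pytest

import notchtsp as nt
from notchtsp.evaluate import EvalError
from conftest import mann_whitney_auc


class TestConfusionMetrics:
    def test_sensitivity_44_of_50(self):
        m = nt.confusion_metrics(nt.ConfusionCounts(tp=44, fp=10, tn=15, fn=6))
        assert m["sensitivity"] == pytest.approx(0.88)

    def test_sensitivity_45_of_46_rounds_to_98_percent(self):
        m = nt.confusion_metrics(nt.ConfusionCounts(tp=45, fp=5, tn=20, fn=1))
        assert m["sensitivity"] == pytest.approx(45 / 46)
        assert round(100 * m["sensitivity"]) == 98

    def test_mcc_hand_example(self):
        # (3·2 − 1·0) / sqrt(4·3·3·2) = 6/sqrt(72)
        m = nt.confusion_metrics(nt.ConfusionCounts(tp=3, fp=1, tn=2, fn=0))
        assert m["mcc"] == pytest.approx(6 / math.sqrt(72))

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        for counts in [(10, 3, 7, 2), (1, 1, 1, 1), (40, 0, 5, 5)]:
            m = nt.confusion_metrics(nt.ConfusionCounts(*counts))
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2
            )

    def test_undefined_metric_reported_as_nan_others_computed(self):
        m = nt.confusion_metrics(nt.ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        assert math.isnan(m["sensitivity"])
        assert m["specificity"] == pytest.approx(0.6)
        assert m["mcc"] == 0.0  # zero marginal rule

    def test_from_labels(self):
        counts = nt.ConfusionCounts.from_labels(
            ["RD", "RD", "pCR", "pCR"], ["RD", "pCR", "pCR", "RD"]
        )
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = nt.roc_auc([0.9, 0.8, 0.2, 0.1], ["RD", "RD", "pCR", "pCR"])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = nt.roc_auc([0.5] * 6, ["RD"] * 3 + ["pCR"] * 3)
        assert auc == 0.5

    def test_four_point_example(self):
        auc, _ = nt.roc_auc([0.9, 0.8, 0.4, 0.3], ["RD", "pCR", "RD", "pCR"])
        assert auc == pytest.approx(0.75)

    def test_matches_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            labels = np.where(y == 1, "RD", "pCR")
            auc, _ = nt.roc_auc(scores, labels)
            assert abs(auc - mann_whitney_auc(scores, y)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(EvalError):
            nt.roc_auc([0.1, 0.2], ["RD", "RD"])


def brute_force_average_precision(scores, y):
    """Step-wise PR area by exhaustive threshold enumeration."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(-scores, kind="stable")
    prev_recall, area = 0.0, 0.0
    total_pos = y.sum()
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        tp = int((y[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / total_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


class TestPrAuc:
    def test_perfect_ranking(self):
        ap, _ = nt.pr_auc([0.9, 0.8, 0.2, 0.1], ["RD", "RD", "pCR", "pCR"])
        assert ap == 1.0

    def test_constant_scores_equal_prevalence(self):
        ap, _ = nt.pr_auc([0.5] * 10, ["RD"] * 3 + ["pCR"] * 7)
        assert ap == pytest.approx(0.3)

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 2, size=n)
            if y.sum() == 0:
                continue
            labels = np.where(y == 1, "RD", "pCR")
            ap, _ = nt.pr_auc(scores, labels)
            assert ap == pytest.approx(brute_force_average_precision(scores, y))

    def test_no_positives_rejected(self):
        with pytest.raises(EvalError):
            nt.pr_auc([0.1, 0.2], ["pCR", "pCR"])


def permutation_p_auc_above_half(scores, y, n_perm=20_000, seed=0):
    """Label-shuffle oracle for the one-sided test of AUC > 0.5."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    m = int(y.sum())
    n = y.size - m
    ranks = rankdata(scores)
    obs = (ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pos = rng.choice(y.size, size=m, replace=False)
        auc = (ranks[pos].sum() - m * (m + 1) / 2) / (m * n)
        hits += auc >= obs
    return hits / n_perm


class TestDeLongVsHalf:
    def test_symmetric_scores_give_z_zero(self):
        scores = [0.1, 0.9, 0.1, 0.9]
        res = nt.delong_vs_half(scores, ["RD", "RD", "pCR", "pCR"])
        assert res.auc == 0.5 and res.z == 0.0 and res.p == 0.5

    def test_constant_scores_flagged_degenerate(self):
        res = nt.delong_vs_half([1.0] * 8, ["RD"] * 4 + ["pCR"] * 4)
        assert res.degenerate and res.p == 1.0

    def test_structural_components_hand_example(self):
        # pos {3, 2, 1}, neg {2.5, 0.5, 0}: V10 = [2/3, 2/3, 2/3]... computed
        # by hand below and compared against the implementation's variance
        scores = np.array([3.0, 2.0, 1.0, 2.5, 0.5, 0.0])
        labels = ["RD"] * 3 + ["pCR"] * 3
        v10 = np.array([3 / 3, 2 / 3, 2 / 3])
        v01 = np.array([1 / 3, 3 / 3, 3 / 3])
        auc_hand = v10.mean()
        var_hand = v10.var(ddof=1) / 3 + v01.var(ddof=1) / 3
        res = nt.delong_vs_half(scores, labels)
        assert res.auc == pytest.approx(auc_hand)
        assert res.se == pytest.approx(math.sqrt(var_hand))

    def test_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(17)
        y = np.array([1] * 20 + [0] * 20)
        scores = rng.normal(0.6 * y, 1.0)
        labels = np.where(y == 1, "RD", "pCR")
        res = nt.delong_vs_half(scores, labels)
        p_perm = permutation_p_auc_above_half(scores, y)
        assert abs(res.p - p_perm) < 0.02

    def test_p_decreases_with_separation(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 30)
        labels = np.where(y == 1, "RD", "pCR")
        noise = rng.normal(size=60)
        ps = []
        for shift in [0.0, 0.4, 0.8, 1.2, 1.6]:
            ps.append(nt.delong_vs_half(noise + shift * y, labels).p)
        assert ps == sorted(ps, reverse=True)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 15 + [0] * 25)
        scores = rng.normal(y * 0.8, 1.0)
        res = nt.delong_vs_half(scores, np.where(y == 1, "RD", "pCR"))
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0


def paired_bootstrap_p(scores_a, scores_b, y, n_boot=10_000, seed=0):
    """Bootstrap oracle: P(bootstrap AUC difference <= 0) for H1: a > b."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    n = y.size
    hits = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        m = yb.sum()
        if m in (0, n):
            continue
        ra = rankdata(scores_a[idx])
        rb = rankdata(scores_b[idx])
        auc_a = (ra[yb == 1].sum() - m * (m + 1) / 2) / (m * (n - m))
        auc_b = (rb[yb == 1].sum() - m * (m + 1) / 2) / (m * (n - m))
        hits += (auc_a - auc_b) <= 0
    return hits / n_boot


class TestDeLongPaired:
    def test_identical_scores_give_p_one(self):
        scores = np.linspace(0, 1, 10)
        labels = ["RD"] * 5 + ["pCR"] * 5
        res = nt.delong_paired(scores, scores, labels)
        assert res.p == 1.0 and res.degenerate

    def test_perfect_vs_antiranked(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 10 + [0] * 10)
        labels = np.where(y == 1, "RD", "pCR")
        base = rng.normal(size=20)
        a = y + 0.1 * base  # perfectly ranks
        res = nt.delong_paired(a, -a, labels)
        assert res.p < 0.01

    def test_p_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(23)
        y = np.array([1] * 30 + [0] * 30)
        labels = np.where(y == 1, "RD", "pCR")
        shared = rng.normal(size=60)
        a = shared + 0.9 * y + rng.normal(scale=0.5, size=60)
        b = shared + 0.4 * y + rng.normal(scale=0.5, size=60)
        res = nt.delong_paired(a, b, labels)
        p_boot = paired_bootstrap_p(a, b, y)
        assert abs(res.p - p_boot) < 0.02


class TestEvaluatePredictions:
    def test_report_fields_consistent(self, default_sim):
        _, cohort, pheno, truth = default_sim
        z = nt.zscore_by_dataset(cohort)
        sig = nt.TSPSignature(
            [nt.ScoredPair(u, d) for u, d in truth["planted_pairs"]],
            vote_threshold=2,
        )
        preds = nt.predict(z, sig)
        report = nt.evaluate_predictions(preds, pheno.response())
        assert 0.9 < report.auc_roc <= 1.0
        assert report.auc_ci_low <= report.auc_roc <= report.auc_ci_high
        assert report.balanced_accuracy == pytest.approx(
            (report.sensitivity + report.specificity) / 2
        )
        assert report.n == report.n_rd + report.n_pcr


def harness_data(seed=0, n_train=150, n_test=100, signal=True):
    rng = np.random.default_rng(seed)

    def make(n, prefix):
        y = rng.integers(0, 2, size=n)
        rows = {"SIG": (3.0 if signal else 0.0) * y + rng.normal(size=n)}
        for i in range(8):
            rows[f"G{i}"] = rng.normal(size=n)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"{prefix}{i}" for i in range(n)]
        labels = pd.Series(
            np.where(y == 1, "RD", "pCR"), index=expr.columns
        )
        return nt.ExpressionCohort(expr), labels

    return make(n_train, "tr"), make(n_test, "te")


class TestLogisticHarness:
    def test_planted_signal_gene_reaches_high_auc(self):
        (train, y_tr), (test, y_te) = harness_data(seed=1)
        lists = {"planted": ["SIG"], "noise": ["G0", "G1", "G2"]}
        res = nt.logistic_signature_harness(
            train, y_tr, test, y_te, lists, reference="planted"
        )
        table = res.table.set_index("signature")
        assert table.loc["planted", "auc"] > 0.95
        assert table.loc["planted", "delong_p_vs_reference"] == 1.0

    def test_null_lists_stay_near_chance(self):
        (train, y_tr), (test, y_te) = harness_data(seed=2, signal=False)
        lists = {f"l{i}": [f"G{i}", f"G{i+1}"] for i in range(4)}
        res = nt.logistic_signature_harness(
            train, y_tr, test, y_te, lists, reference="l0"
        )
        assert (res.table["auc"] - 0.5).abs().max() < 0.1

    def test_deterministic(self):
        (train, y_tr), (test, y_te) = harness_data(seed=3)
        lists = {"a": ["SIG", "G0"], "b": ["G1", "G2"]}
        r1 = nt.logistic_signature_harness(train, y_tr, test, y_te, lists, "a")
        r2 = nt.logistic_signature_harness(train, y_tr, test, y_te, lists, "a")
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_unmeasured_list_skipped_with_warning(self):
        (train, y_tr), (test, y_te) = harness_data(seed=4)
        lists = {"good": ["SIG"], "ghost": ["NOT_A_GENE"]}
        with pytest.warns(UserWarning, match="ghost"):
            res = nt.logistic_signature_harness(
                train, y_tr, test, y_te, lists, reference="good"
            )
        assert res.skipped == ["ghost"]
        assert list(res.table["signature"]) == ["good"]

    def test_external_reference_scores(self):
        (train, y_tr), (test, y_te) = harness_data(seed=5)
        ref = np.linspace(0, 1, test.n_samples)
        res = nt.logistic_signature_harness(
            train, y_tr, test, y_te, {"a": ["SIG"]}, reference=ref
        )
        assert len(res.table) == 1
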