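import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    auc_pair_count,
    average_precision_cuts,
    bootstrap_auc_diff_var,
    fisher_enumeration,
    ks_ecdf_sweep,
)
from conftest import random_scores_labels
from selv.benchmark import (
    HIGHER,
    LOWER,
    benchmark_report,
    compare_auc,
    fisher_2x2,
    ks_two_sample,
    pr,
    report_table,
    roc,
)
from selv.errors import DomainError, SingleClassError


class TestRoc:
    def test_perfect_separation_low_scores_pathogenic(self):
        result = roc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], LOWER)
        assert result.auc == 1.0

    def test_all_ties_give_half(self):
        assert roc([3.0] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_curve_endpoints_and_monotonicity(self, rng):
        for _ in range(20):
            scores, labels = random_scores_labels(rng, 40, n_distinct=8)
            result = roc(scores, labels)
            assert (result.fpr[0], result.tpr[0]) == (0.0, 0.0)
            assert (result.fpr[-1], result.tpr[-1]) == (1.0, 1.0)
            assert np.all(np.diff(result.fpr) >= 0)
            assert np.all(np.diff(result.tpr) >= 0)
            assert result.auc == pytest.approx(
                np.trapezoid(result.tpr, result.fpr), abs=1e-15
            )

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            scores, labels = random_scores_labels(
                rng, int(rng.integers(4, 200)), n_distinct=int(rng.integers(2, 30))
            )
            assert roc(scores, labels).auc == pytest.approx(
                auc_pair_count(scores, labels), abs=1e-12
            )

    def test_orientation_flip_complements_auc(self, rng):
        for _ in range(50):
            scores, labels = random_scores_labels(rng, 60, n_distinct=10)
            assert roc(scores, labels, HIGHER).auc + roc(
                scores, labels, LOWER
            ).auc == pytest.approx(1.0, abs=1e-15)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores, labels = random_scores_labels(rng, 80, n_distinct=12)
            assert roc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_auc_invariant_under_increasing_transform(self, data):
        n = data.draw(st.integers(4, 30))
        # quantized scores so the float transform cannot merge distinct values
        scores = np.array(data.draw(
            st.lists(st.floats(-5, 5).map(lambda x: round(x, 3)),
                     min_size=n, max_size=n)
        ))
        labels = np.array(
            data.draw(st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n))
        )
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = np.exp(scores) + 3 * scores
        assert roc(transformed, labels).auc == pytest.approx(
            roc(scores, labels).auc, abs=1e-12
        )

    def test_single_class_and_mismatch_errors(self):
        with pytest.raises(SingleClassError):
            roc([1.0, 2.0], [1, 1])
        with pytest.raises(DomainError):
            roc([1.0, 2.0], [1, 0, 1])


class TestPr:
    def test_perfect_separation(self):
        assert pr([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], LOWER).pr_auc == 1.0

    def test_all_ties_give_prevalence(self):
        result = pr([2.0] * 8, [1, 1, 0, 0, 0, 0, 0, 0])
        assert result.pr_auc == pytest.approx(0.25)

    def test_recall_spans_unit_interval(self, rng):
        scores, labels = random_scores_labels(rng, 50, n_distinct=7)
        result = pr(scores, labels)
        assert result.recall[0] == 0.0
        assert result.recall[-1] == 1.0

    def test_matches_exhaustive_cut_oracle(self, rng):
        for _ in range(100):
            scores, labels = random_scores_labels(
                rng, int(rng.integers(4, 200)), n_distinct=int(rng.integers(2, 30))
            )
            assert pr(scores, labels).pr_auc == pytest.approx(
                average_precision_cuts(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            scores, labels = random_scores_labels(rng, 80, n_distinct=12)
            assert pr(scores, labels).pr_auc == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestCompareAuc:
    def test_identical_scores_give_null_result(self, rng):
        scores, labels = random_scores_labels(rng, 40, n_distinct=10)
        result = compare_auc(scores, scores.copy(), labels)
        assert result.d_statistic == 0.0
        assert result.p_value == 1.0
        assert result.n_paired == 40

    def test_monotone_transform_gives_zero_d(self, rng):
        scores, labels = random_scores_labels(rng, 40, n_distinct=10)
        result = compare_auc(scores, np.exp(scores), labels)
        assert result.d_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.auc_a == pytest.approx(result.auc_b, abs=1e-15)

    def test_antisymmetric_in_argument_order(self, rng):
        for _ in range(10):
            labels = np.r_[np.ones(15, int), np.zeros(15, int)]
            a, b = rng.normal(size=30), rng.normal(size=30)
            ab = compare_auc(a, b, labels)
            ba = compare_auc(b, a, labels)
            assert ab.d_statistic == pytest.approx(-ba.d_statistic, abs=1e-12)
            assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_orientation_makes_lower_is_pathogenic_comparable(self, rng):
        scores, labels = random_scores_labels(rng, 40, n_distinct=10)
        result = compare_auc(
            -scores, scores, labels, orientation_a=LOWER, orientation_b=HIGHER
        )
        assert result.d_statistic == pytest.approx(0.0, abs=1e-12)

    def test_variance_close_to_paired_bootstrap(self):
        # the analytic DeLong variance should track a stratified paired
        # bootstrap of the AUC difference on correlated scores
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = n = 60
            labels = np.r_[np.ones(m, int), np.zeros(n, int)]
            base = np.r_[rng.normal(1.0, 1, m), rng.normal(0, 1, n)]
            sa = base + rng.normal(0, 0.7, m + n)
            sb = base + rng.normal(0, 0.7, m + n)
            result = compare_auc(sa, sb, labels)
            boot = bootstrap_auc_diff_var(rng, sa, sb, labels, reps=2000)
            assert result.var_diff == pytest.approx(boot, rel=0.15)


class TestKsTwoSample:
    def test_identical_samples_give_zero(self):
        sample = [0.1, 0.5, 0.9, 0.5]
        assert ks_two_sample(sample, list(sample)).d == 0.0

    def test_disjoint_singletons_give_one(self):
        assert ks_two_sample([0.0], [1.0]).d == 1.0

    def test_matches_ecdf_sweep_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 500))
            b = rng.normal(0.3, 1.1, size=rng.integers(2, 500))
            result = ks_two_sample(a, b)
            assert result.d == pytest.approx(ks_ecdf_sweep(a, b), abs=1e-12)
            assert 0.0 <= result.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            ks_two_sample([], [1.0])


class TestFisher2x2:
    def test_homogeneous_table(self):
        result = fisher_2x2([[5, 5], [5, 5]])
        assert result.p_value == 1.0
        assert result.odds_ratio == pytest.approx(1.0)

    def test_complete_separation(self):
        result = fisher_2x2([[10, 0], [0, 10]])
        assert math.isinf(result.odds_ratio)
        assert result.p_value == pytest.approx(
            fisher_enumeration([[10, 0], [0, 10]]), abs=1e-12
        )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            table = rng.integers(0, 16, size=(2, 2))
            if table.sum() == 0:
                table[0, 0] = 1
            assert fisher_2x2(table).p_value == pytest.approx(
                fisher_enumeration(table.tolist()), abs=1e-10
            )

    def test_invariant_under_transposition(self, rng):
        for _ in range(20):
            table = rng.integers(0, 20, size=(2, 2)) + 1
            assert fisher_2x2(table).p_value == pytest.approx(
                fisher_2x2(table.T).p_value, abs=1e-12
            )

    def test_rejects_negative_and_fractional_cells(self):
        with pytest.raises(DomainError):
            fisher_2x2([[1, 2], [-1, 3]])
        with pytest.raises(DomainError):
            fisher_2x2([[1.5, 2], [1, 3]])


class TestBenchmarkReport:
    def _frame(self, rng, n=200):
        import pandas as pd

        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        selv = rng.exponential(0.3, n) * (1 - 0.5 * labels)
        competitor = -selv + rng.normal(0, 0.1, n)
        frame = pd.DataFrame({
            "contig": "chr1", "position": np.arange(1, n + 1),
            "ref": "A", "alt": "G", "label": labels,
            "context": "splice_site", "selv": selv, "n_variants": 1,
            "ada_score": competitor,
        })
        frame.loc[rng.choice(n, 30, replace=False), "ada_score"] = np.nan
        return frame

    def test_structure_one_competitor(self, rng):
        report = benchmark_report(self._frame(rng))
        assert set(report["scores"]) == {"selv", "ada_score"}
        assert set(report["comparisons"]) == {"ada_score"}
        assert report["scores"]["ada_score"]["n_dropped"] == 30
        assert report["comparisons"]["ada_score"]["n_paired"] == 170

    def test_report_aucs_equal_direct_calls(self, rng):
        frame = self._frame(rng)
        report = benchmark_report(frame)
        sub = frame[frame["ada_score"].notna()]
        direct = roc(sub["ada_score"], sub["label"].astype(int), HIGHER).auc
        assert report["scores"]["ada_score"]["auc"] == pytest.approx(direct)
        direct_selv = roc(frame["selv"], frame["label"].astype(int), LOWER).auc
        assert report["scores"]["selv"]["auc"] == pytest.approx(direct_selv)

    def test_negated_selv_competitor_matches_selv(self, rng):
        frame = self._frame(rng)
        frame["mirror"] = -frame["selv"]
        report = benchmark_report(frame, score_columns=["mirror"])
        assert report["comparisons"]["mirror"]["d_statistic"] == pytest.approx(
            0.0, abs=1e-12
        )
        assert report["scores"]["mirror"]["auc"] == pytest.approx(
            report["scores"]["selv"]["auc"]
        )

    def test_selv_only_report_is_not_an_error(self, rng):
        frame = self._frame(rng).drop(columns=["ada_score"])
        report = benchmark_report(frame)
        assert set(report["scores"]) == {"selv"}
        assert report["comparisons"] == {}
        assert len(report_table(report)) == 1
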