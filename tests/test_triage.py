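"""Ensemble voting, threshold triage, metrics, and the patient bootstrap."""

import numpy as np
import pytest

from ahre.triage import (
    CLASS_NAMES,
    PredictionSet,
    patient_bootstrap,
    per_class_metrics,
    soft_vote,
    triage_classify,
    evaluate_at_thresholds,
    workload_report,
)


def _pset(probs, true=None, patients=None, ids=None):
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    return PredictionSet(
        episode_ids=ids or [f"e{i}" for i in range(n)],
        probs=probs,
        true_labels=None if true is None else np.asarray(true),
        patient_ids=patients,
    )


def _random_pset(rng, n):
    raw = rng.dirichlet(np.ones(3), size=n)
    return _pset(raw, true=rng.integers(0, 3, n))


class TestSoftVote:
    def test_identical_sets_idempotent(self):
        s = _random_pset(np.random.default_rng(0), 20)
        out = soft_vote([s, s, s])
        np.testing.assert_allclose(out.probs, s.probs)
        assert out.provenance == "ensemble"

    def test_elementwise_mean(self):
        a = _pset([[1.0, 0.0, 0.0]])
        b = _pset([[0.0, 1.0, 0.0]])
        np.testing.assert_allclose(soft_vote([a, b]).probs, [[0.5, 0.5, 0.0]])

    def test_output_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        sets = [_random_pset(rng, 15) for _ in range(4)]
        for s in sets[1:]:
            s.episode_ids = list(sets[0].episode_ids)
        out = soft_vote(sets)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_key_mismatch_rejected(self):
        a = _pset([[1.0, 0.0, 0.0]], ids=["x"])
        b = _pset([[1.0, 0.0, 0.0]], ids=["y"])
        with pytest.raises(ValueError):
            soft_vote([a, b])


class TestTriageClassify:
    def test_high_confidence_retained(self):
        pred, kept = triage_classify(_pset([[0.98, 0.01, 0.01]]), 0.95)
        assert pred[0] == 0 and kept[0]

    def test_low_confidence_not_retained(self):
        pred, kept = triage_classify(_pset([[0.60, 0.30, 0.10]]), 0.95)
        assert pred[0] == 0 and not kept[0]

    def test_tie_prefers_ataf_then_noise(self):
        pred, _ = triage_classify(_pset([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4]]), None)
        assert pred.tolist() == [0, 1]

    def test_coverage_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        s = _random_pset(rng, 400)
        coverages = []
        for tau in np.linspace(0.0, 1.0, 21):
            _, kept = triage_classify(s, tau)
            coverages.append(kept.mean())
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))


class TestPerClassMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 2])
        r = per_class_metrics(y, y)
        assert r.incorrect == 0
        assert np.allclose(r.per_class["precision_pct"], 100.0)
        assert np.allclose(r.per_class["recall_pct"], 100.0)

    def test_hand_computed_confusion(self):
        # class 0: TP=3, FP=1, FN=1, TN=5
        y_true = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        y_pred = np.array([0, 0, 0, 1, 0, 1, 1, 2, 2, 2])
        r = per_class_metrics(y_pred, y_true)
        row = r.per_class.iloc[0]
        assert row["precision_pct"] == pytest.approx(75.0)
        assert row["recall_pct"] == pytest.approx(75.0)
        assert row["specificity_pct"] == pytest.approx(100 * 5 / 6, abs=0.01)
        assert row["f2_pct"] == pytest.approx(75.0)

    def test_cross_checked_against_sklearn(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        r = per_class_metrics(y_pred, y_true)
        p = precision_score(y_true, y_pred, average=None, zero_division=np.nan) * 100
        s = recall_score(y_true, y_pred, average=None, zero_division=np.nan) * 100
        np.testing.assert_allclose(r.per_class["precision_pct"], p, atol=1e-9)
        np.testing.assert_allclose(r.per_class["recall_pct"], s, atol=1e-9)

    def test_undefined_ratios_reported_as_nan(self):
        # FFO never true nor predicted among retained
        y_true = np.array([0, 0, 1])
        y_pred = np.array([0, 0, 1])
        r = per_class_metrics(y_pred, y_true)
        ffo = r.per_class[r.per_class["class"] == "FFO"].iloc[0]
        assert np.isnan(ffo["precision_pct"]) and np.isnan(ffo["recall_pct"])

    def test_standard_definitions_not_the_swapped_printed_ones(self):
        """Precision = TP/(TP+FP) and recall = TP/(TP+FN). A widely-seen
        typographical variant swaps the denominators (precision over TP+FN,
        recall over TP+FP); on an asymmetric confusion the two readings
        differ, and this package uses the standard one."""
        # class 0: TP=6, FP=2, FN=4
        y_true = np.array([0] * 10 + [1] * 5)
        y_pred = np.array([0] * 6 + [1] * 4 + [0] * 2 + [1] * 3)
        r = per_class_metrics(y_pred, y_true).per_class.iloc[0]
        assert r["precision_pct"] == pytest.approx(100 * 6 / 8)   # not 6/10
        assert r["recall_pct"] == pytest.approx(100 * 6 / 10)     # not 6/8
        swapped_precision = 100 * 6 / 10
        assert r["precision_pct"] != pytest.approx(swapped_precision)

    def test_f2_equals_closed_form_on_grid(self):
        # Eq. identity: 5/(1/P + 4/R) == 5PR/(4P+R)
        for p in np.linspace(0.05, 1.0, 20):
            for r in np.linspace(0.05, 1.0, 20):
                harmonic = 5 / (1 / p + 4 / r)
                closed = 5 * p * r / (4 * p + r)
                assert abs(harmonic - closed) < 1e-12


class TestWorkloadReport:
    def test_unthresholded_row_has_full_coverage_and_error_rate_definition(self):
        rng = np.random.default_rng(4)
        s = _random_pset(rng, 100)
        reports = evaluate_at_thresholds(s, (0.5, 0.9))
        table = workload_report(reports)
        assert table.iloc[0]["coverage_pct"] == 100.0
        for _, row in table.iterrows():
            if row["retained"]:
                assert row["error_rate_pct"] == pytest.approx(
                    100.0 * row["incorrect"] / row["retained"]
                )

    def test_retained_counts_non_increasing(self):
        rng = np.random.default_rng(5)
        s = _random_pset(rng, 300)
        reports = evaluate_at_thresholds(s, (0.90, 0.95))
        r = [rep.retained for rep in reports]
        assert r[0] >= r[1] >= r[2]
        assert r[0] == 300


class TestPatientBootstrap:
    def test_all_correct_gives_100_recall_zero_width_ci(self):
        probs = np.tile([0.9, 0.05, 0.05], (12, 1))
        true = np.zeros(12, dtype=int)
        patients = [f"p{i % 4}" for i in range(12)]
        s = _pset(probs, true, patients)
        res = patient_bootstrap(s, n_iterations=50, rng=np.random.default_rng(0))
        row = res.recall.iloc[0]
        assert row["point_pct"] == 100.0
        assert row["ci_lo_pct"] == row["ci_hi_pct"] == 100.0

    def test_single_patient_single_episode_degenerate(self):
        s = _pset([[0.8, 0.1, 0.1]], true=[0], patients=["p0"])
        res = patient_bootstrap(s, n_iterations=25, rng=np.random.default_rng(1))
        row = res.recall.iloc[0]
        assert row["ci_lo_pct"] == row["ci_hi_pct"] == row["point_pct"] == 100.0

    def test_invalid_iteration_count(self):
        s = _pset([[1.0, 0.0, 0.0]], true=[0], patients=["p0"])
        with pytest.raises(ValueError):
            patient_bootstrap(s, n_iterations=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet(np.ones(3), 40)
        s = _pset(probs, rng.integers(0, 3, 40), [f"p{i % 10}" for i in range(40)])
        r1 = patient_bootstrap(s, n_iterations=40, rng=np.random.default_rng(7))
        r2 = patient_bootstrap(s, n_iterations=40, rng=np.random.default_rng(7))
        assert r1.recall.equals(r2.recall)

    def test_ci_width_shrinks_with_patient_count(self):
        def width(n_patients, seed):
            rng = np.random.default_rng(seed)
            n = n_patients * 3
            true = np.zeros(n, dtype=int)
            # 15% miss rate -> nondegenerate sampling distribution
            wrong = rng.random(n) < 0.15
            probs = np.where(wrong[:, None], [0.1, 0.8, 0.1], [0.8, 0.1, 0.1])
            s = _pset(probs, true, [f"p{i % n_patients}" for i in range(n)])
            res = patient_bootstrap(s, n_iterations=300, rng=np.random.default_rng(seed))
            row = res.recall.iloc[0]
            return row["ci_hi_pct"] - row["ci_lo_pct"]

        assert width(400, 8) < width(50, 8)
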