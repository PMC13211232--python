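"""Evaluator: metrics against brute-force oracles, threshold calibration."""

import numpy as np
import pytest

from bedfall.evaluate import (
    UndefinedMetricError,
    auprc,
    auroc,
    calibrate_threshold,
    evaluate,
    mse,
    per_posture_report,
    thresholded_metrics,
)

# ---------------------------------------------------------------------------
# independent oracles


def auroc_pairwise(scores, labels):
    """Exhaustive positive-negative pair comparison, ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def auprc_stepwise(scores, labels):
    """Step integration of the PR curve at every unique-score threshold."""
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    total_pos = l.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # all samples tied at this score
            tp += l[j] == 1
            fp += l[j] == 0
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def best_f1_sweep(scores, labels):
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    return max(thresholded_metrics(scores, labels, t)[3] for t in candidates)


def _random_instance(rng, n=30, ties=False):
    scores = rng.integers(0, 8, n) / 8.0 if ties else rng.random(n)
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    return scores, labels


class TestRankingMetricOracles:
    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for k in range(500):
            scores, labels = _random_instance(rng, ties=(k % 3 == 0))
            assert auroc(scores, labels) == pytest.approx(
                auroc_pairwise(scores, labels), abs=1e-12
            )

    def test_auprc_matches_stepwise_oracle(self):
        rng = np.random.default_rng(1)
        for k in range(500):
            scores, labels = _random_instance(rng, ties=(k % 3 == 0))
            assert auprc(scores, labels) == pytest.approx(
                auprc_stepwise(scores, labels), abs=1e-12
            )

    def test_perfect_and_inverted_separation(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auroc(scores, labels) == 1.0
        assert auprc(scores, labels) == 1.0
        assert auroc(scores, 1 - labels) == 0.0

    def test_constant_scores_auprc_equals_prevalence(self):
        labels = np.array([1, 0, 0, 1, 0])
        assert auprc(np.full(5, 0.5), labels) == pytest.approx(0.4)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores, labels = _random_instance(rng, n=50)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(auroc(scores, labels), abs=1e-12)

    def test_label_inversion_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)  # tie-free
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) + auroc(scores, 1 - labels) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))
        with pytest.raises(UndefinedMetricError):
            auprc(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_random_scorer_auprc_near_half_at_balanced_prevalence(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(200):
            scores = rng.random(200)
            labels = np.tile([0, 1], 100)
            vals.append(auprc(scores, labels))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


class TestThresholdCalibration:
    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(5)
        for k in range(300):
            scores, labels = _random_instance(rng, n=50, ties=(k % 4 == 0))
            tau = calibrate_threshold(scores, labels)
            f1_at_tau = thresholded_metrics(scores, labels, tau)[3]
            assert f1_at_tau == pytest.approx(best_f1_sweep(scores, labels), abs=1e-12)

    def test_separated_scores_yield_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert calibrate_threshold(scores, labels) == pytest.approx(0.5)

    def test_all_equal_scores_choose_the_better_trivial_classifier(self):
        scores = np.full(6, 0.3)
        labels = np.array([1, 1, 1, 1, 0, 0])
        tau = calibrate_threshold(scores, labels)
        # predicting all positive gives F1 = 2*(4/6)/(4/6+1) = 0.8 > 0
        assert tau < 0.3
        assert thresholded_metrics(scores, labels, tau)[3] == pytest.approx(0.8)


class TestThresholdedMetrics:
    def test_perfect_predictions(self):
        scores = np.array([0.9, 0.2])
        labels = np.array([1, 0])
        assert thresholded_metrics(scores, labels, 0.5) == (1.0, 1.0, 1.0, 1.0)

    def test_contingency_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], float)
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        acc, prec, rec, f1 = thresholded_metrics(scores, labels, 0.5)
        assert (acc, prec, rec, f1) == (0.8, 0.75, 0.75, 0.75)

    def test_no_predicted_positives_convention(self):
        scores = np.array([0.1, 0.2, 0.3])
        labels = np.array([1, 0, 1])
        acc, prec, rec, f1 = thresholded_metrics(scores, labels, 0.9)
        assert (prec, rec, f1) == (0.0, 0.0, 0.0)


class TestMse:
    def test_hand_cases_and_oracle(self):
        assert mse(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == 1.0
        assert mse(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b = rng.random(20), rng.random(20)
            acc = 0.0
            for x, y in zip(a, b):
                acc += (x - y) ** 2
            assert mse(a, b) == pytest.approx(acc / 20, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mse(np.array([]), np.array([]))


class TestSubgroupReports:
    def test_identical_subgroups_get_identical_reports(self):
        scores = np.tile([0.9, 0.7, 0.3, 0.1], 4)
        labels = np.tile([1, 1, 0, 0], 4)
        y = np.tile([0.8, 0.6, 0.0, 0.0], 4)
        modes = np.repeat(["supine", "prone", "left_lateral", "right_lateral"], 4)
        reports = per_posture_report(scores, labels, y, modes, tau=0.5)
        assert len(reports) == 5
        per_mode = [r for r in reports if r.subgroup != "overall"]
        first = per_mode[0]
        for r in per_mode[1:]:
            assert r.auroc == first.auroc and r.f1 == first.f1 and r.mse == first.mse

    def test_pooled_mse_is_weighted_subgroup_mean(self):
        rng = np.random.default_rng(7)
        n = 40
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        labels[:4] = [0, 1, 0, 1]
        y = rng.random(n)
        modes = rng.choice(["supine", "prone"], n)
        reports = per_posture_report(scores, labels, y, modes, tau=0.5)
        overall = next(r for r in reports if r.subgroup == "overall")
        subs = [r for r in reports if r.subgroup != "overall"]
        weighted = sum(r.mse * r.n_samples for r in subs) / sum(r.n_samples for r in subs)
        assert overall.mse == pytest.approx(weighted, abs=1e-12)

    def test_single_class_subgroup_gets_nan_ranking_metrics(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0])
        y = np.array([0.9, 0.8, 0.5, 0.0])
        modes = np.array(["supine", "supine", "prone", "prone"])
        reports = per_posture_report(scores, labels, y, modes, tau=0.5)
        supine = next(r for r in reports if r.subgroup == "supine")
        assert np.isnan(supine.auroc)
        prone = next(r for r in reports if r.subgroup == "prone")
        assert np.isfinite(prone.auroc)
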