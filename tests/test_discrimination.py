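"""ROC/AUROC, DeLong CI, operating points and model-vs-rater tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dermastress.data import RaterTable, Manifest, ImageRecord
from dermastress.discrimination import (
    OperatingPoint,
    aupr,
    compare_aurocs,
    compare_model_to_raters,
    operating_point_at,
    rater_points,
    roc_with_delong_ci,
    sensitivity_matched_threshold,
)
from dermastress.errors import DegenerateInputError, InsufficientDataError
from tests.conftest import make_pset

import pandas as pd


def pairwise_auroc(pos, neg):
    """Independent oracle: exhaustive concordance count over all pairs."""
    wins = sum(
        1.0 if x > y else (0.5 if x == y else 0.0)
        for x, y in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_separation(self):
        ps = make_pset([0.9, 0.8, 0.1, 0.2],
                       ["melanoma", "melanoma", "nevus", "nevus"])
        assert roc_with_delong_ci(ps).auroc == 1.0

    def test_complete_ties_give_half(self):
        ps = make_pset([0.5] * 6, ["melanoma"] * 3 + ["nevus"] * 3)
        assert roc_with_delong_ci(ps).auroc == pytest.approx(0.5)

    def test_single_class_is_degenerate(self):
        ps = make_pset([0.4, 0.6], ["nevus", "nevus"])
        with pytest.raises(DegenerateInputError):
            roc_with_delong_ci(ps)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = 10, 10
        # quantize to force ties in some instances
        scores = np.round(rng.random(n_pos + n_neg), 1)
        labels = ["melanoma"] * n_pos + ["nevus"] * n_neg
        ps = make_pset(scores, labels)
        oracle = pairwise_auroc(scores[:n_pos], scores[n_pos:])
        assert roc_with_delong_ci(ps).auroc == pytest.approx(oracle, abs=1e-12)

    def test_ci_contains_point_estimate_and_is_clipped(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.beta(4, 2, 30), rng.beta(2, 4, 30)])
        ps = make_pset(scores, ["melanoma"] * 30 + ["nevus"] * 30)
        roc = roc_with_delong_ci(ps, 0.95)
        lo, hi = roc.auroc_ci
        assert 0.0 <= lo <= roc.auroc <= hi <= 1.0

    def test_roc_monotone_along_thresholds(self, delta5_test_set):
        roc = roc_with_delong_ci(delta5_test_set)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)


class TestAUPR:
    def test_perfect_ranking(self):
        ps = make_pset(
            [0.9, 0.8, 0.7, 0.65, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05],
            ["melanoma"] * 5 + ["nevus"] * 5,
        )
        assert aupr(ps) == pytest.approx(1.0)

    def test_single_positive_ranked_last(self):
        # PR steps: the only positive is found at rank n -> AP = 1/n
        n = 8
        scores = np.linspace(0.9, 0.2, n)
        labels = ["nevus"] * (n - 1) + ["melanoma"]
        ps = make_pset(scores, labels)
        assert aupr(ps) == pytest.approx(1.0 / n)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(42)
        n = 4000
        labels = ["melanoma" if u < 0.3 else "nevus" for u in rng.random(n)]
        ps = make_pset(rng.random(n), labels)
        prev = labels.count("melanoma") / n
        assert aupr(ps) == pytest.approx(prev, abs=0.03)

    def test_no_positives_degenerate(self):
        ps = make_pset([0.2, 0.4], ["nevus", "nevus"])
        with pytest.raises(DegenerateInputError):
            aupr(ps)


class TestSensitivityMatchedThreshold:
    PS = staticmethod(
        lambda: make_pset(
            [0.9, 0.6, 0.3, 0.5, 0.2],
            ["melanoma", "melanoma", "melanoma", "nevus", "nevus"],
        )
    )

    def test_target_one_recalls_all_positives(self):
        op = sensitivity_matched_threshold(self.PS(), 1.0)
        assert op.sensitivity == 1.0
        assert op.threshold < 0.3  # strictly below the minimum positive score

    def test_target_zero_allows_empty_recall(self):
        op = sensitivity_matched_threshold(self.PS(), 0.0)
        assert op.threshold == 1.0
        assert op.sensitivity == 0.0

    def test_two_thirds_target_enumerated(self):
        # enumerating all candidate thresholds: sens >= 2/3 first holds
        # strictly between the 0.5 negative and the 0.6 positive
        op = sensitivity_matched_threshold(self.PS(), 0.66)
        assert 0.5 < op.threshold <= 0.6
        assert op.sensitivity == pytest.approx(2 / 3)
        # both negatives (0.5, 0.2) fall at or below the threshold
        assert op.specificity == pytest.approx(1.0)

    def test_monotone_in_target(self):
        ps = self.PS()
        thresholds = [
            sensitivity_matched_threshold(ps, t).threshold
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_youden_identity(self):
        op = operating_point_at(self.PS(), 0.4)
        assert op.youden == pytest.approx(op.sensitivity + op.specificity - 1)


def _manifest_and_raters(decisions):
    """decisions: {rater: {image_id: 0/1}}; truth fixed per image."""
    truth = {"m1": "melanoma", "m2": "melanoma", "n1": "nevus", "n2": "nevus"}
    mf = Manifest(
        [ImageRecord(i, i, "d", "test", t) for i, t in truth.items()],
        ("melanoma", "nevus"),
    )
    rows = [
        {"rater_id": r, "image_id": i, "decision": d}
        for r, dec in decisions.items()
        for i, d in dec.items()
    ]
    return mf, RaterTable(pd.DataFrame(rows))


class TestRaterPoints:
    def test_biopsy_everything_rater(self):
        mf, rt = _manifest_and_raters(
            {"r1": {"m1": 1, "m2": 1, "n1": 1, "n2": 1}}
        )
        rs = rater_points(rt, mf, "melanoma")
        p = rs.points[0]
        assert (p.sensitivity, p.specificity) == (1.0, 0.0)

    def test_oracle_rater(self):
        mf, rt = _manifest_and_raters(
            {"r1": {"m1": 1, "m2": 1, "n1": 0, "n2": 0}}
        )
        p = rater_points(rt, mf, "melanoma").points[0]
        assert (p.sensitivity, p.specificity) == (1.0, 1.0)

    def test_noisy_raters_match_confusion_counts(self, rng):
        truth = {"m1": "melanoma", "m2": "melanoma", "n1": "nevus", "n2": "nevus"}
        decisions = {
            f"r{k}": {
                i: int(rng.random() < (0.8 if t == "melanoma" else 0.3))
                for i, t in truth.items()
            }
            for k in range(3)
        }
        mf, rt = _manifest_and_raters(decisions)
        rs = rater_points(rt, mf, "melanoma")
        for p in rs.points:
            dec = decisions[p.rater_id]
            tp = sum(dec[i] for i in ("m1", "m2"))
            tn = sum(1 - dec[i] for i in ("n1", "n2"))
            assert p.sensitivity == pytest.approx(tp / 2)
            assert p.specificity == pytest.approx(tn / 2)
        assert rs.roc_area == pytest.approx(
            (rs.mean_sensitivity + rs.mean_specificity) / 2
        )

    def test_one_class_rater_excluded(self):
        mf, rt = _manifest_and_raters(
            {"r1": {"m1": 1, "m2": 0}, "r2": {"m1": 1, "m2": 1, "n1": 0, "n2": 1}}
        )
        rs = rater_points(rt, mf, "melanoma")
        assert rs.excluded == ["r1"]
        assert [p.rater_id for p in rs.points] == ["r2"]


def _rater_summary(youdens):
    from dermastress.discrimination import RaterPoint, RaterSummary

    pts = [RaterPoint(f"r{i}", 0.5, 0.5, y, y, 10) for i, y in enumerate(youdens)]
    return RaterSummary(pts, 0.5, 0.5, 0.5, [])


class TestCompareModelToRaters:
    def _model(self, youden):
        # OperatingPoint with sens+spec-1 == youden
        return OperatingPoint(0.5, (1 + youden) / 2, (1 + youden) / 2, f1=youden)

    def test_identical_constant_raters_degenerate(self):
        s = compare_model_to_raters(self._model(0.5), _rater_summary([0.5, 0.5, 0.5]))
        assert s.p_value == 1.0
        assert s.mean_difference == 0.0
        assert s.degenerate

    def test_symmetric_sample_gives_p_one(self):
        s = compare_model_to_raters(self._model(0.5), _rater_summary([0.4, 0.5, 0.6]))
        assert s.p_value == pytest.approx(1.0)
        assert s.mean_difference == pytest.approx(0.0)

    def test_matches_closed_form_t(self):
        vals = np.array([0.2, 0.3, 0.4])
        model = 0.6
        s = compare_model_to_raters(self._model(model), _rater_summary(list(vals)))
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        t_oracle = (vals.mean() - model) / se
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=len(vals) - 1)
        assert s.statistic == pytest.approx(t_oracle)
        assert s.p_value == pytest.approx(p_oracle)
        assert s.mean_difference == pytest.approx(vals.mean() - model)

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_model_to_raters(self._model(0.5), _rater_summary([0.4]))


def ranksum_exact_p(a, b):
    """Exhaustive enumeration oracle for the two-sided rank-sum test."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # distinct values only
    observed = sum(ranks[v] for v in a)
    n = len(a)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(sums)
    tail = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return tail / len(sums)


class TestCompareAUROCs:
    def test_identical_samples_p_one(self):
        s = compare_aurocs([0.7, 0.8, 0.9], [0.9, 0.7, 0.8])
        assert s.p_value == 1.0
        assert s.degenerate

    def test_exact_small_sample(self):
        s = compare_aurocs([1, 2, 3], [4, 5, 6])
        assert s.p_value == pytest.approx(0.1)
        assert s.p_value == pytest.approx(ranksum_exact_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_agrees_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = list(np.round(rng.random(4), 6))
        b = list(np.round(rng.random(5), 6))
        s = compare_aurocs(a, b)
        assert s.p_value == pytest.approx(ranksum_exact_p(a, b))

    def test_large_sample_matches_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.80, 0.02, 40)
        b = rng.normal(0.82, 0.02, 40)
        s = compare_aurocs(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert s.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_aurocs([], [0.5])


class TestYoudenBehaviour:
    def test_random_classifier_youden_near_zero(self):
        rng = np.random.default_rng(11)
        n = 4000
        labels = ["melanoma" if u < 0.5 else "nevus" for u in rng.random(n)]
        ps = make_pset(rng.random(n), labels)
        op = operating_point_at(ps, 0.5)
        assert abs(op.youden) < 0.05

    def test_perfect_classifier_youden_one(self):
        ps = make_pset([0.9, 0.8, 0.1, 0.2],
                       ["melanoma", "melanoma", "nevus", "nevus"])
        assert operating_point_at(ps, 0.5).youden == pytest.approx(1.0)
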