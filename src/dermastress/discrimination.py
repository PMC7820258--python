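"""ROC discrimination metrics, human-matched operating points, model-vs-rater tests.

AUROC here is the Mann-Whitney concordance probability: the chance a
randomly chosen positive (melanoma) image is scored above a randomly
chosen negative (nevus) one, ties counted half. Confidence intervals use
DeLong's nonparametric structural-components variance estimator, which is
authored here because no installed dependency provides it; the point
estimate is delegated to scikit-learn and cross-checked in the test suite
against exhaustive pair enumeration.

Threshold semantics throughout the toolkit: an image is called positive
iff its positive-class probability is *strictly greater* than the
threshold (``p > t``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .data import PredictionSet, RaterTable, Manifest
from .errors import DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCCurve:
    """ROC operating points plus AUROC with its DeLong confidence interval."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray  # non-decreasing along the array
    specificity: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    level: float
    auroc_se: float


@dataclass(frozen=True)
class OperatingPoint:
    """A probability threshold with the metrics realized at it.

    ``provenance`` records how the threshold was chosen (e.g. matched to
    the mean rater sensitivity), since the same number means different
    things under different matching rules.
    """

    threshold: float
    sensitivity: float
    specificity: float
    provenance: str = ""
    f1: float = float("nan")

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class TestSummary:
    """Outcome of one statistical comparison."""

    statistic: float
    p_value: float
    mean_difference: float
    test: str
    significant: bool
    degenerate: bool = False


def _binary_arrays(pset: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    """(y, scores) on original, in-distribution records."""
    sub = pset.filter(originals_only=True, include_ood=False)
    y = sub.y_true()
    return y, sub.positive_scores()


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong variance from positive/negative scores.

    Structural components: V10_i = mean_j psi(X_i, Y_j) and
    V01_j = mean_i psi(X_i, Y_j) with psi = 1 / 0.5 / 0 for X > / = / < Y.
    Computed with midranks, O((m+n) log(m+n)).
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)  # midranks on pooled sample
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_with_delong_ci(pset: PredictionSet, level: float = 0.95) -> ROCCurve:
    """ROC curve with AUROC and its DeLong confidence interval.

    Only original (untransformed), in-distribution records enter. Raises
    :class:`DegenerateInputError` if a single class is present (AUROC is
    undefined without both).
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    y, s = _binary_arrays(pset)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("AUROC undefined: only one class present")
    auc_sk = float(roc_auc_score(y, s))
    auc, var = _delong_variance(s[y == 1], s[y == 0])
    assert abs(auc - auc_sk) < 1e-10  # two routes to the same concordance
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    fpr, tpr, thr = roc_curve(y, s)
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auroc=auc,
        auroc_ci=(lo, hi),
        level=level,
        auroc_se=se,
    )


def aupr(pset: PredictionSet) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated).

    Equals average precision; lies in [prevalence, 1].
    """
    y, s = _binary_arrays(pset)
    if not np.any(y == 1):
        raise DegenerateInputError("AUPR undefined: no positive records")
    return float(average_precision_score(y, s))


def confusion_at_threshold(
    y: np.ndarray, scores: np.ndarray, threshold: float
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) under the strict rule: positive iff score > threshold."""
    pred = scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def operating_point_at(
    pset: PredictionSet, threshold: float, provenance: str = ""
) -> OperatingPoint:
    """Realized sensitivity/specificity/F1 at a fixed threshold."""
    y, s = _binary_arrays(pset)
    tp, fp, tn, fn = confusion_at_threshold(y, s, threshold)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return OperatingPoint(threshold, sens, spec, provenance=provenance, f1=f1)


def sensitivity_matched_threshold(
    pset: PredictionSet, target_sensitivity: float
) -> OperatingPoint:
    """Largest threshold whose sensitivity meets or exceeds the target.

    Mirrors matching a model's operating point to a human benchmark's
    sensitivity. Candidate thresholds are midpoints between consecutive
    distinct scores plus sentinels beyond both extremes, so the returned
    threshold sits strictly between score levels; because specificity is
    non-decreasing in the threshold, the largest qualifying threshold also
    maximizes specificity.
    """
    if not 0 <= target_sensitivity <= 1:
        raise ValueError("target sensitivity must be in [0, 1]")
    y, s = _binary_arrays(pset)
    if not np.any(y == 1):
        raise DegenerateInputError("no positive records to match sensitivity on")
    uniq = np.unique(s)
    below_min = uniq[0] / 2.0 if uniq[0] > 0 else -0.5
    candidates = [1.0, *((uniq[1:] + uniq[:-1]) / 2.0)[::-1], below_min]
    for t in candidates:  # descending; strict rule makes 1.0 recall nothing
        tp, fp, tn, fn = confusion_at_threshold(y, s, t)
        sens = tp / (tp + fn)
        if sens >= target_sensitivity:
            spec = tn / (tn + fp) if tn + fp else float("nan")
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            return OperatingPoint(
                float(t),
                sens,
                spec,
                provenance=f"matched to target sensitivity {target_sensitivity}",
                f1=f1,
            )
    raise AssertionError("unreachable: the below-minimum candidate recalls everything")


@dataclass(frozen=True)
class RaterPoint:
    rater_id: str
    sensitivity: float
    specificity: float
    youden: float
    f1: float
    n_decisions: int


@dataclass(frozen=True)
class RaterSummary:
    points: list[RaterPoint]
    mean_sensitivity: float
    mean_specificity: float
    roc_area: float  # polygon (0,0) -> mean point -> (1,1): (sens+spec)/2
    excluded: list[str]


def rater_points(
    raters: RaterTable, manifest: Manifest, positive_class: str
) -> RaterSummary:
    """Per-rater sensitivity/specificity from management decisions vs truth.

    A rater is the human analogue of one operating point. The aggregate
    rater ROC area is the area of the polygon (0,0) → mean rater point →
    (1,1) in ROC space, i.e. (mean sensitivity + mean specificity) / 2 —
    the standard single-point construction. Raters who decided images of
    only one class are excluded with a logged warning.
    """
    raters.validate_against(manifest)
    points: list[RaterPoint] = []
    excluded: list[str] = []
    for rid, grp in raters.decisions.groupby("rater_id"):
        truth = np.array(
            [manifest[i].true_label == positive_class for i in grp["image_id"]]
        )
        dec = grp["decision"].to_numpy().astype(bool)
        if truth.all() or not truth.any():
            excluded.append(str(rid))
            logger.warning("rater %s decided only one class; excluded", rid)
            continue
        tp = int(np.sum(dec & truth))
        fn = int(np.sum(~dec & truth))
        tn = int(np.sum(~dec & ~truth))
        fp = int(np.sum(dec & ~truth))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        points.append(
            RaterPoint(str(rid), sens, spec, sens + spec - 1.0, f1, len(grp))
        )
    if not points:
        raise InsufficientDataError("no rater had decisions on both classes")
    ms = float(np.mean([p.sensitivity for p in points]))
    msp = float(np.mean([p.specificity for p in points]))
    return RaterSummary(points, ms, msp, (ms + msp) / 2.0, excluded)


def compare_model_to_raters(
    model_point: OperatingPoint,
    rater_summary: RaterSummary,
    metric: str = "youden",
) -> TestSummary:
    """Two-sided one-sample t-test of per-rater metric values vs the model's.

    ``metric`` is ``"youden"`` or ``"f1"``. The reported mean difference is
    directional (raters minus model). A zero-variance rater sample
    short-circuits the test: the difference is reported exactly and p is 1
    when it is zero (no test can distinguish identical constants).
    """
    if metric not in ("youden", "f1"):
        raise ValueError("metric must be 'youden' or 'f1'")
    vals = np.array([getattr(p, metric) for p in rater_summary.points], dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError("need at least two raters to compare")
    model_val = getattr(model_point, metric)
    diff = float(vals.mean() - model_val)
    if np.ptp(vals) == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        return TestSummary(float("nan"), p, diff, "one-sample t (degenerate)",
                           p < 0.05, degenerate=True)
    t, p = stats.ttest_1samp(vals, model_val)
    return TestSummary(float(t), float(p), diff, "one-sample t", p < 0.05)


def compare_aurocs(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TestSummary:
    """Wilcoxon rank-sum test on two samples of per-replicate AUROCs.

    Replicates are typically ensemble members or bootstrap resamples.
    Exact null distribution when the combined sample has at most 20
    values and no cross-sample ties; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("empty AUROC sample")
    if np.array_equal(np.sort(a), np.sort(b)):
        return TestSummary(float("nan"), 1.0, 0.0, "wilcoxon rank-sum", False,
                           degenerate=True)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestSummary(
        float(res.statistic),
        float(res.pvalue),
        float(a.mean() - b.mean()),
        f"wilcoxon rank-sum ({method})",
        res.pvalue < 0.05,
    )
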