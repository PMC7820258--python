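"""Selective prediction: RRA curves, AURRA, gambler's loss, OOD confidence audits.

Selective prediction lets a classifier commit only on its most confident
cases and defer the rest to a human. The response-rate accuracy (RRA)
curve makes this operational: rank the test set by descending confidence
and plot, against each coverage c (the fraction of the set evaluated),
the accuracy among the top ceil(c*n) predictions. Its area (AURRA)
summarizes how well confidence orders correctness.

The gambler's loss gives a model an explicit reject output during
training: for payoff o > 1 the per-example loss is

    -log( p_true + p_reject / o )

so hedging mass onto the reject output is worth 1/o of a correct
prediction — cross-entropy is the o -> infinity (or p_reject = 0) limit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import PredictionSet
from .discrimination import TestSummary
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RRACurve:
    coverages: tuple[float, ...]  # strictly increasing, in (0, 1]
    accuracies: tuple[float, ...]
    aurra: float  # mean of accuracies over the grid
    aurra_trapezoid: float  # trapezoid area on the unit coverage interval
    tie_broken: bool  # confidence ties were broken by image_id order


def _ranked_correct(pset: PredictionSet) -> np.ndarray:
    """Correctness sorted by descending confidence, ties by image_id."""
    sub = pset.filter(originals_only=True)
    conf = sub.confidences()
    ids = [r.image_id for r in sub.records]
    order = sorted(range(len(sub)), key=lambda i: (-conf[i], ids[i]))
    return sub.correct()[order], len(np.unique(conf)) < len(conf)


def rra_curve(
    pset: PredictionSet, coverage_grid: Sequence[float] | str = "all"
) -> RRACurve:
    """Response-rate accuracy curve over a coverage grid.

    Correctness is argmax-class vs true label (binary: melanoma probability
    > 0.5). ``"all"`` uses the full per-record grid {k/n : k = 1..n}, the
    grid AURRA is defined on.
    """
    correct, tie_broken = _ranked_correct(pset)
    n = len(correct)
    if n == 0:
        raise ValueError("empty prediction set")
    prefix = np.cumsum(correct)
    if isinstance(coverage_grid, str):
        if coverage_grid != "all":
            raise ValueError("coverage_grid must be a list or 'all'")
        ks = np.arange(1, n + 1)
        coverages = ks / n
    else:
        coverages = np.asarray(sorted(coverage_grid), dtype=float)
        if len(coverages) == 0:
            raise ValueError("coverage grid is empty")
        if np.any(coverages <= 0) or np.any(coverages > 1):
            raise ValueError("coverages must lie in (0, 1]")
        if len(np.unique(coverages)) < len(coverages):
            raise ValueError("coverage grid has duplicates")
        # tiny epsilon so c = k/n maps to exactly k despite float round-off
        ks = np.ceil(coverages * n - 1e-9).astype(int)
        ks = np.clip(ks, 1, n)
    accs = prefix[ks - 1] / ks
    mean = float(accs.mean())
    trap = float(np.trapezoid(accs, coverages) / (coverages[-1] - coverages[0])) \
        if len(coverages) > 1 else float(accs[0])
    return RRACurve(
        coverages=tuple(float(c) for c in coverages),
        accuracies=tuple(float(a) for a in accs),
        aurra=mean,
        aurra_trapezoid=trap,
        tie_broken=tie_broken,
    )


def aurra(curve: RRACurve) -> float:
    """AURRA: mean RRA over the coverage grid (use the full grid)."""
    return curve.aurra


def compare_aurra(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TestSummary:
    """Two-sided Wilcoxon signed-rank test on paired AURRA samples.

    Exact null distribution for n <= 25 non-zero differences without tied
    absolute differences; normal approximation otherwise. All-zero
    differences are degenerate: p = 1 (the samples are identical).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise InsufficientDataError("paired samples must have equal length")
    if len(a) < 2:
        raise InsufficientDataError("need at least two pairs")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return TestSummary(float("nan"), 1.0, 0.0, "wilcoxon signed-rank", False,
                           degenerate=True)
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                         zero_method="wilcox")
    return TestSummary(
        float(res.statistic), float(res.pvalue), float(d.mean()),
        f"wilcoxon signed-rank ({method})", res.pvalue < 0.05,
    )


# ---------------------------------------------------------------------------
# Gambler outputs
# ---------------------------------------------------------------------------

DEFAULT_PAYOFF = 2.2


@dataclass
class GamblerBatch:
    """Outputs of a rejection-capable model: class probs plus a reject mass.

    ``probs`` is (n, k+1) with the last column the rejection mass; every
    row sums to 1. ``payoff`` is the gambler's o > 1. The default
    rejection decision rule is the reciprocal-payoff threshold
    ``p_reject > 1/o``.
    """

    probs: np.ndarray
    payoff: float = DEFAULT_PAYOFF

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.payoff <= 1:
            raise ValueError(f"payoff must exceed 1, got {self.payoff}")
        if self.probs.ndim != 2 or self.probs.shape[1] < 2:
            raise ValueError("probs must be (n, k+1) with k >= 1 classes")
        if np.any(self.probs < -1e-9) or np.any(
            np.abs(self.probs.sum(axis=1) - 1) > 1e-6
        ):
            raise ValueError("each row of probs must be a distribution")

    @property
    def reject_mass(self) -> np.ndarray:
        return self.probs[:, -1]

    def class_probs(self, renormalize: bool = True) -> np.ndarray:
        cp = self.probs[:, :-1]
        if renormalize:
            s = cp.sum(axis=1, keepdims=True)
            cp = np.divide(cp, s, out=np.full_like(cp, 1 / cp.shape[1]), where=s > 0)
        return cp

    def reject_decisions(self, threshold: float | None = None) -> np.ndarray:
        if threshold is None:
            threshold = 1.0 / self.payoff
        return self.reject_mass > threshold


def gambler_loss(batch: GamblerBatch, true_idx: Sequence[int]) -> float:
    """Mean gambler's loss -log(p_true + p_reject / o) over a batch.

    With zero rejection mass this is exactly the cross-entropy. Log
    arguments are clamped at 1e-12 (with a warning) so a fully wrong,
    fully committed output yields a large finite loss.
    """
    y = np.asarray(true_idx, dtype=int)
    if len(y) != len(batch.probs):
        raise ValueError("true_idx length mismatch")
    arg = batch.probs[np.arange(len(y)), y] + batch.reject_mass / batch.payoff
    if np.any(arg < 1e-12):
        warnings.warn("gambler loss argument clamped at 1e-12", stacklevel=2)
        arg = np.clip(arg, 1e-12, None)
    return float(-np.mean(np.log(arg)))


@dataclass(frozen=True)
class RejectionRate:
    group: str
    n: int
    n_rejected: int
    rate: float
    ci_low: float
    ci_high: float


def rejection_rates(
    batch: GamblerBatch,
    groups: Sequence[str],
    threshold: float | None = None,
    level: float = 0.95,
) -> list[RejectionRate]:
    """Per-group fraction of examples whose rejection mass exceeds threshold.

    ``groups`` assigns every row a group name (e.g. melanoma / nevus /
    actinic_keratosis); a well-behaved rejector rejects OOD groups at a
    higher rate than in-distribution ones. CIs are exact (Clopper-Pearson)
    binomial intervals. Empty groups are omitted with a warning.
    """
    groups = list(groups)
    if len(groups) != len(batch.probs):
        raise ValueError("groups must label every row of the batch")
    rejected = batch.reject_decisions(threshold)
    out = []
    for g in sorted(set(groups)):
        mask = np.asarray([x == g for x in groups])
        n = int(mask.sum())
        if n == 0:
            logger.warning("group %s is empty; omitted", g)
            continue
        k = int(rejected[mask].sum())
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=level,
                                                 method="exact")
        out.append(RejectionRate(g, n, k, k / n, float(ci.low), float(ci.high)))
    return out


# ---------------------------------------------------------------------------
# OOD confidence audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot summary: hinges at quartiles, 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]),
        n=len(x),
    )


@dataclass(frozen=True)
class OODComparison:
    in_class: str
    ood_class: str
    p_value: float
    method: str
    in_stats: BoxplotStats
    ood_stats: BoxplotStats


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), method


def ood_confidence_audit(
    in_dist: PredictionSet,
    ood_sets: dict[str, PredictionSet],
) -> list[OODComparison]:
    """Compare prediction confidence on trained-on vs never-seen classes.

    For every (in-distribution class, OOD class) pair, the two confidence
    samples are compared by a two-sided Wilcoxon rank-sum test and each is
    summarized with Tukey boxplot statistics. In-distribution confidence
    is the max class probability; OOD records, which have no in-set true
    class, are scored by the positive-class (melanoma) probability — a
    trustworthy model should not assert melanoma on a seborrheic keratosis
    as confidently as on a melanoma.
    """
    sub = in_dist.filter(originals_only=True, include_ood=False)
    if len(sub) == 0:
        raise ValueError("empty in-distribution set")
    out = []
    for in_class in sub.class_names:
        grp = sub.filter(true_label=in_class)
        if len(grp) == 0:
            logger.warning("no in-distribution records of class %s", in_class)
            continue
        in_conf = grp.confidences()
        for ood_class, ood in sorted(ood_sets.items()):
            osub = ood.filter(originals_only=True)
            if len(osub) == 0:
                raise ValueError(f"empty OOD set for class {ood_class!r}")
            ood_conf = osub.positive_scores()
            p, method = _rank_sum(in_conf, ood_conf)
            out.append(
                OODComparison(
                    in_class=in_class,
                    ood_class=ood_class,
                    p_value=p,
                    method=f"wilcoxon rank-sum ({method})",
                    in_stats=boxplot_stats(in_conf),
                    ood_stats=boxplot_stats(ood_conf),
                )
            )
    return out
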