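"""Temperature-scaling calibration and RMS calibration error.

Temperature scaling rescales a model's logits by a single fitted scalar
T > 0 before the softmax: ``p = softmax(z / T)``. T is chosen to minimize
the mean negative log-likelihood on a held-out validation split. Because
dividing by a positive scalar is monotone, calibration never changes any
prediction's argmax class or any pairwise ranking — discrimination
metrics (AUROC) are invariant under it.

Calibration quality is summarized by the L2 (root-mean-square) calibration
error over equal-mass confidence bins:

    RMSE = sqrt( sum_b  mass_b * (mean_conf_b - accuracy_b)^2 )

which is 0 for a perfectly calibrated model and 1 for a maximally
miscalibrated one (always certain, always wrong).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

from .data import PredictionRecord, PredictionSet, softmax
from .errors import ContractError
from .selective import rra_curve

logger = logging.getLogger(__name__)

_T_BOUNDS = (0.05, 20.0)


class TemperatureScaler(BaseEstimator, TransformerMixin):
    """Single-parameter post-hoc calibrator (sklearn-style estimator).

    Parameters
    ----------
    bounds : (float, float)
        Search interval for the temperature. The scalar minimization runs
        on log T inside these bounds, which guarantees termination and
        covers all practical miscalibration.

    Attributes
    ----------
    temperature_ : float
        Fitted temperature T.
    nll_before_, nll_after_ : float
        Mean negative log-likelihood on the fitting data at T=1 and at
        the fitted T. ``nll_after_ <= nll_before_`` always (T=1 is inside
        the search interval).
    converged_ : bool
        Whether the scalar optimizer reported success.
    """

    def __init__(self, bounds: tuple[float, float] = _T_BOUNDS):
        self.bounds = bounds

    @staticmethod
    def _nll(logits: np.ndarray, y_idx: np.ndarray, T: float) -> float:
        p = softmax(logits / T)
        eps = np.clip(p[np.arange(len(y_idx)), y_idx], 1e-300, None)
        return float(-np.mean(np.log(eps)))

    def fit(self, logits: np.ndarray, y_idx: np.ndarray) -> "TemperatureScaler":
        """Fit T on (n, k) logits and integer class indices."""
        logits = np.asarray(logits, dtype=float)
        y_idx = np.asarray(y_idx, dtype=int)
        if logits.ndim != 2 or len(logits) != len(y_idx):
            raise ContractError("logits must be (n, k) aligned with y_idx")
        lo, hi = self.bounds
        res = minimize_scalar(
            lambda logT: self._nll(logits, y_idx, float(np.exp(logT))),
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        self.temperature_ = float(np.exp(res.x))
        self.converged_ = bool(res.success)
        if not res.success:
            logger.warning("temperature search did not converge: %s", res.message)
        self.nll_before_ = self._nll(logits, y_idx, 1.0)
        self.nll_after_ = self._nll(logits, y_idx, self.temperature_)
        if self.nll_after_ > self.nll_before_ + 1e-9:  # T=1 is always a candidate
            self.temperature_, self.nll_after_ = 1.0, self.nll_before_
        return self

    def transform(self, logits: np.ndarray) -> np.ndarray:
        """Calibrated probabilities softmax(logits / T_)."""
        return softmax(np.asarray(logits, dtype=float) / self.temperature_)


@dataclass(frozen=True)
class TemperatureModel:
    """Fitted temperature with its fit diagnostics."""

    temperature: float
    fit_nll_before: float
    fit_nll_after: float
    converged: bool


def _logits_matrix(pset: PredictionSet, allow_reconstruct: bool = False) -> np.ndarray:
    have = [r.logits is not None for r in pset.records]
    if all(have) and pset.records:
        return np.asarray([r.logits for r in pset.records], dtype=float)
    if not allow_reconstruct:
        raise ContractError("prediction set has no logits; temperature scaling needs them")
    # Log-probabilities are valid logits up to an additive shift, to which
    # softmax is invariant at T=1 but not at T!=1: an approximation.
    warnings.warn(
        "reconstructing logits as log-probabilities (approximation)", stacklevel=3
    )
    P = np.clip(pset.probs_matrix(), 1e-12, None)
    return np.log(P)


def _y_index(pset: PredictionSet) -> np.ndarray:
    names = pset.class_names
    return np.asarray([names.index(t) for t in pset.true_labels()], dtype=int)


def fit_temperature(
    validation: PredictionSet, *, allow_probability_logits: bool = False
) -> TemperatureModel:
    """Fit a temperature on a validation split (in-distribution originals).

    Requires logits; with ``allow_probability_logits`` the log-probabilities
    stand in for score tables that ship no logits.
    """
    sub = validation.filter(originals_only=True, include_ood=False)
    Z = _logits_matrix(sub, allow_reconstruct=allow_probability_logits)
    if len(np.unique(sub.y_true())) < 2:
        raise ContractError("temperature fitting needs both classes present")
    scaler = TemperatureScaler().fit(Z, _y_index(sub))
    return TemperatureModel(
        scaler.temperature_, scaler.nll_before_, scaler.nll_after_, scaler.converged_
    )


def apply_temperature(
    pset: PredictionSet, model: TemperatureModel, *, allow_probability_logits: bool = False
) -> PredictionSet:
    """Replace probabilities with softmax(logits / T); rank-preserving."""
    Z = _logits_matrix(pset, allow_reconstruct=allow_probability_logits)
    Zs = Z / model.temperature
    P = softmax(Zs)
    records = [
        PredictionRecord(r.image_id, tuple(P[i]), logits=tuple(Zs[i]),
                         transform_id=r.transform_id)
        for i, r in enumerate(pset.records)
    ]
    return PredictionSet(records, pset.manifest, pset.positive_class)


@dataclass(frozen=True)
class CalibrationBin:
    mass: float
    mean_confidence: float
    accuracy: float
    count: int


@dataclass(frozen=True)
class CalibrationReport:
    rmse: float
    bins: list[CalibrationBin]
    num_bins_requested: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "num_bins_requested": self.num_bins_requested,
            "bins": [
                {
                    "mass": b.mass,
                    "mean_confidence": b.mean_confidence,
                    "accuracy": b.accuracy,
                    "count": b.count,
                }
                for b in self.bins
            ],
        }


def rms_calibration_error(pset: PredictionSet, num_bins: int = 15) -> CalibrationReport:
    """L2 calibration error over equal-mass confidence bins.

    Records are sorted by confidence and partitioned into ``num_bins``
    near-equal-count bins (adaptive binning — robust when the confidence
    distribution is skewed toward 1, as it typically is post-softmax).
    Records with identical confidence are kept in the same bin. When there
    are fewer records than bins the bin count drops to the record count
    with a logged warning.
    """
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    sub = pset.filter(originals_only=True, include_ood=False)
    n = len(sub)
    if n == 0:
        raise ValueError("empty prediction set")
    if n < num_bins:
        logger.warning("only %d records for %d bins; reducing", n, num_bins)
        eff_bins = n
    else:
        eff_bins = num_bins
    conf = sub.confidences()
    correct = sub.correct().astype(float)
    order = np.argsort(conf, kind="stable")
    conf, correct = conf[order], correct[order]
    # equal-mass boundaries at count quantiles, merged across ties
    edges = [round(i * n / eff_bins) for i in range(eff_bins + 1)]
    bins: list[CalibrationBin] = []
    start = 0
    for e in edges[1:]:
        end = max(e, start)
        # extend so equal confidences never straddle a boundary
        while 0 < end < n and conf[end] == conf[end - 1]:
            end += 1
        if end <= start:
            continue
        c = conf[start:end]
        a = correct[start:end]
        bins.append(
            CalibrationBin(
                mass=(end - start) / n,
                mean_confidence=float(c.mean()),
                accuracy=float(a.mean()),
                count=end - start,
            )
        )
        start = end
    rmse = float(
        np.sqrt(sum(b.mass * (b.mean_confidence - b.accuracy) ** 2 for b in bins))
    )
    return CalibrationReport(rmse=rmse, bins=bins, num_bins_requested=num_bins)


@dataclass(frozen=True)
class CoverageGap:
    coverage: float
    expected: float
    observed: float
    difference: float  # observed - expected


def expected_observed_gap(
    test: PredictionSet,
    validation: PredictionSet,
    coverage_grid: Sequence[float],
    *,
    mode: str = "coverage",
) -> list[CoverageGap]:
    """Expected vs observed selective accuracy at each coverage.

    Observed accuracy is the test set's response-rate accuracy (RRA) at
    coverage c; expected accuracy is the validation set's. A model whose
    development-time calibration generalizes shows difference ~ 0; an
    overconfident model shows observed < expected.

    ``mode="coverage"`` matches validation accuracy at the same coverage
    fraction (the default); ``mode="threshold"`` instead matches at the
    test set's confidence cutoff realized at that coverage.
    """
    grid = list(coverage_grid)
    if not grid:
        raise ValueError("coverage grid is empty")
    if mode not in ("coverage", "threshold"):
        raise ValueError("mode must be 'coverage' or 'threshold'")
    obs_curve = rra_curve(test, grid)
    out = []
    for cov, obs in zip(obs_curve.coverages, obs_curve.accuracies):
        if mode == "coverage":
            exp = rra_curve(validation, [cov]).accuracies[0]
        else:
            # accuracy of validation records above the test confidence cutoff
            sub_t = test.filter(originals_only=True, include_ood=False)
            k = int(np.ceil(cov * len(sub_t)))
            cutoff = np.sort(sub_t.confidences())[::-1][k - 1]
            sub_v = validation.filter(originals_only=True, include_ood=False)
            keep = sub_v.confidences() >= cutoff
            exp = (
                float(sub_v.correct()[keep].mean()) if keep.any() else float("nan")
            )
        out.append(CoverageGap(float(cov), float(exp), float(obs), float(obs - exp)))
    return out
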