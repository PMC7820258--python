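"""Full stress-battery orchestration and machine-readable report assembly.

Runs the stages in a fixed order — discrimination, calibration, selective
prediction, OOD audit, replicate consistency, transform sweep, test-time
augmentation — each stage isolated so one failure never silences the
rest. Emits one JSON summary whose every number is re-derivable from the
per-stage CSVs, plus a provenance block (config, seeds, library versions,
tie-break conventions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    apply_temperature,
    expected_observed_gap,
    fit_temperature,
    rms_calibration_error,
)
from .data import Manifest, PredictionSet, Predictor, RaterTable
from .discrimination import (
    compare_model_to_raters,
    operating_point_at,
    rater_points,
    roc_with_delong_ci,
    aupr,
    sensitivity_matched_threshold,
)
from .robustness import (
    TransformSpec,
    default_battery,
    replicate_consistency,
    test_time_augmentation,
    transform_sweep,
)
from .selective import aurra, ood_confidence_audit, rra_curve

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one battery run; every default lands in provenance."""

    positive_class: str = "melanoma"
    target_sensitivity: float = 0.9
    num_bins: int = 15
    coverage_grid: list[float] | str = "all"
    battery: list[TransformSpec] = field(default_factory=default_battery)
    seed: int = 0
    out_dir: str | None = None
    plots: bool = False

    def provenance(self) -> dict:
        return {
            "tool": f"dermastress {__version__}",
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "positive_class": self.positive_class,
            "target_sensitivity": self.target_sensitivity,
            "num_bins": self.num_bins,
            "coverage_grid": self.coverage_grid
            if isinstance(self.coverage_grid, str)
            else list(self.coverage_grid),
            "battery": [s.transform_id for s in self.battery],
            "seed": self.seed,
            "conventions": {
                "decision_rule": "positive iff p(positive_class) > threshold",
                "confidence": "max class probability",
                "rra_tie_break": "descending confidence, ties by image_id",
                "rmse_binning": "equal-mass bins, ties kept together",
            },
        }


@dataclass
class StageResult:
    name: str
    status: str  # ok | skipped | error
    summary: dict = field(default_factory=dict)
    error: str | None = None


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


class BatteryReport:
    def __init__(self, config: RunConfig):
        self.config = config
        self.stages: list[StageResult] = []
        self.tables: dict[str, pd.DataFrame] = {}

    @property
    def failed(self) -> bool:
        return any(s.status == "error" for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "provenance": self.config.provenance(),
            "stages": {
                s.name: {"status": s.status, "error": s.error, **_jsonable(s.summary)}
                for s in self.stages
            },
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(self.to_dict(), indent=1, allow_nan=True))
        return summary_path


def run_stress_battery(
    test: PredictionSet,
    config: RunConfig,
    *,
    validation: PredictionSet | None = None,
    raters: RaterTable | None = None,
    predictor: Predictor | None = None,
    sweep_manifest: Manifest | None = None,
    images: dict[str, np.ndarray] | None = None,
) -> BatteryReport:
    """Execute every applicable stage of the stress battery.

    Stages without their inputs (no rater table, no predictor, no OOD
    records) are marked skipped; a stage that raises is recorded as an
    error and the remaining stages still run.
    """
    report = BatteryReport(config)
    test = PredictionSet(test.records, test.manifest, config.positive_class)

    def stage(name: str):
        def deco(fn):
            try:
                summary = fn()
                report.stages.append(
                    StageResult(name, "ok" if summary is not None else "skipped",
                                summary or {})
                )
            except Exception as exc:  # stage isolation is the contract
                logger.exception("stage %s failed", name)
                report.stages.append(StageResult(name, "error", error=str(exc)))
        return deco

    op_holder: dict[str, Any] = {}

    @stage("discrimination")
    def _disc():
        roc = roc_with_delong_ci(test)
        op = sensitivity_matched_threshold(test, config.target_sensitivity)
        op_holder["op"] = op
        report.tables["roc_curve"] = pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        )
        summary = {
            "auroc": roc.auroc,
            "auroc_ci": list(roc.auroc_ci),
            "ci_level": roc.level,
            "aupr": aupr(test),
            "operating_point": _jsonable(op),
            "youden": op.youden,
        }
        if raters is not None:
            rs = rater_points(raters, test.manifest, config.positive_class)
            report.tables["rater_points"] = pd.DataFrame(
                [_jsonable(p) for p in rs.points]
            )
            summary["raters"] = {
                "mean_sensitivity": rs.mean_sensitivity,
                "mean_specificity": rs.mean_specificity,
                "roc_area": rs.roc_area,
                "youden_vs_model": _jsonable(
                    compare_model_to_raters(op, rs, "youden")
                ),
                "f1_vs_model": _jsonable(compare_model_to_raters(op, rs, "f1")),
            }
        return summary

    def _gap_grid(pset: PredictionSet) -> list[float]:
        n = len(pset.filter(originals_only=True, include_ood=False))
        return [k / n for k in range(1, n + 1)]

    @stage("calibration")
    def _cal():
        pre = rms_calibration_error(test, config.num_bins)
        summary: dict[str, Any] = {"rmse_precalibration": pre.rmse}
        report.tables["calibration_bins_pre"] = pd.DataFrame(
            [_jsonable(b) for b in pre.bins]
        )
        if validation is not None:
            tm = fit_temperature(validation, allow_probability_logits=True)
            cal_test = apply_temperature(test, tm, allow_probability_logits=True)
            post = rms_calibration_error(cal_test, config.num_bins)
            gaps = expected_observed_gap(
                cal_test,
                apply_temperature(validation, tm, allow_probability_logits=True),
                _gap_grid(test),
            )
            report.tables["calibration_bins_post"] = pd.DataFrame(
                [_jsonable(b) for b in post.bins]
            )
            report.tables["coverage_gap"] = pd.DataFrame(
                [_jsonable(g) for g in gaps]
            )
            summary.update(
                {
                    "temperature": tm.temperature,
                    "converged": tm.converged,
                    "rmse_postcalibration": post.rmse,
                    "max_abs_gap": max(abs(g.difference) for g in gaps),
                }
            )
            op_holder["calibrated_test"] = cal_test
        return summary

    @stage("selective_prediction")
    def _sel():
        target = op_holder.get("calibrated_test", test)
        curve = rra_curve(target.filter(include_ood=False), config.coverage_grid)
        report.tables["rra_curve"] = pd.DataFrame(
            {"coverage": curve.coverages, "accuracy": curve.accuracies}
        )
        return {
            "aurra": aurra(curve),
            "aurra_trapezoid": curve.aurra_trapezoid,
            "accuracy": curve.accuracies[-1],
            "tie_broken": curve.tie_broken,
        }

    @stage("ood_audit")
    def _ood():
        ood_labels = sorted(
            {
                test.manifest[r.image_id].true_label
                for r in test.records
                if test.manifest[r.image_id].is_ood
            }
        )
        if not ood_labels:
            return None  # skipped
        ood_sets = {
            lbl: test.filter(true_label=lbl, originals_only=True)
            for lbl in ood_labels
        }
        comps = ood_confidence_audit(test, ood_sets)
        report.tables["ood_audit"] = pd.DataFrame(
            [
                {
                    "in_class": c.in_class,
                    "ood_class": c.ood_class,
                    "p_value": c.p_value,
                    "in_median": c.in_stats.median,
                    "ood_median": c.ood_stats.median,
                }
                for c in comps
            ]
        )
        return {"comparisons": [_jsonable(c) for c in comps]}

    @stage("replicate_consistency")
    def _rep():
        op = op_holder.get("op")
        thr = op.threshold if op is not None else 0.5
        res = replicate_consistency(test, thr)
        report.tables["replicate_verdicts"] = pd.DataFrame(
            [
                {"lesion_id": v.lesion_id, "category": v.category}
                for v in res.verdicts
            ]
        )
        return {
            "threshold": thr,
            "counts": res.category_counts,
            "percentages": res.category_percentages,
            "n_single_image_lesions": res.n_single_image_lesions,
        }

    @stage("transform_sweep")
    def _sweep():
        if predictor is None or sweep_manifest is None:
            return None
        op = op_holder.get("op")
        thr = op.threshold if op is not None else 0.5
        res = transform_sweep(
            predictor,
            sweep_manifest,
            config.battery,
            thr,
            images=images,
            positive_class=config.positive_class,
        )
        report.tables["robustness_verdicts"] = pd.DataFrame(
            [
                {
                    "lesion_id": v.lesion_id,
                    "category": v.category,
                    "flipping_transforms": ";".join(v.flipping_transforms),
                    "max_abs_change": v.max_abs_change,
                }
                for v in res.verdicts
            ]
        )
        return {
            "threshold": thr,
            "counts": res.category_counts,
            "non_robust_fraction": res.non_robust_fraction,
            "median_abs_change": res.median_abs_change,
            "iqr_abs_change": res.iqr_abs_change,
        }

    @stage("test_time_augmentation")
    def _tta():
        if predictor is None or sweep_manifest is None or images is None:
            return None
        rows = []
        for rec in sweep_manifest:
            if rec.is_ood:
                continue
            img = images[rec.image_id]
            orig = np.asarray(predictor(img), dtype=float)
            avg = test_time_augmentation(predictor, img, config.battery)
            rows.append(
                {
                    "image_id": rec.image_id,
                    "true_label": rec.true_label,
                    "p_original": orig[0],
                    "p_tta": avg[0],
                }
            )
        df = pd.DataFrame(rows)
        report.tables["tta"] = df
        y = (df["true_label"] == config.positive_class).to_numpy().astype(int)
        from sklearn.metrics import roc_auc_score

        if len(np.unique(y)) < 2:
            return {"note": "single-class sweep set; AUROC comparison skipped"}
        return {
            "auroc_original": float(roc_auc_score(y, df["p_original"])),
            "auroc_tta": float(roc_auc_score(y, df["p_tta"])),
        }

    if config.out_dir:
        report.write(config.out_dir)
        if config.plots:
            try:
                render_plots(report, config.out_dir)
            except Exception:
                logger.exception("plot rendering failed")
    return report


def render_plots(report: BatteryReport, out_dir: str | Path) -> list[Path]:
    """Render optional figures (ROC, RRA, reliability) from the emitted CSVs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    specs = [
        ("roc_curve", lambda df, ax: ax.plot(1 - df["specificity"], df["sensitivity"]),
         ("1 - specificity", "sensitivity")),
        ("rra_curve", lambda df, ax: ax.plot(df["coverage"], df["accuracy"]),
         ("coverage", "accuracy")),
        ("calibration_bins_pre",
         lambda df, ax: (ax.plot(df["mean_confidence"], df["accuracy"], "o-"),
                         ax.plot([0, 1], [0, 1], "--", color="gray")),
         ("mean confidence", "accuracy")),
    ]
    for name, draw, (xl, yl) in specs:
        csv = out / f"{name}.csv"
        if not csv.exists():
            continue
        df = pd.read_csv(csv)
        fig, ax = plt.subplots(figsize=(4, 4))
        draw(df, ax)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
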