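"""Robustness to image-capture variation: transforms, sweeps, replicate consistency.

Two complementary audits of a classifier's stability at a fixed decision
threshold:

* **Transform sweep** — re-predict each lesion's image under a battery of
  capture-plausible transformations (rotations, horizontal flip, mild
  brightness/contrast changes) and categorize each lesion by whether its
  thresholded call survives: consistently correct, consistently wrong,
  correct-original-but-wrong-transformed, or wrong-original-but-correct-
  transformed. The pooled |Δp| across all (image, transform) pairs is
  summarized by median and IQR.
* **Replicate consistency** — lesions photographed several times in one
  visit should receive the same call on every photograph; each multi-image
  lesion is classed all-correct, all-wrong, or mixed.

Both use the strict decision rule: positive iff p(positive class) > t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .data import Manifest, PredictionSet, Predictor, apply_predictor
from .discrimination import OperatingPoint

logger = logging.getLogger(__name__)

TRANSFORM_KINDS = ("rotation", "horizontal_flip", "brightness", "contrast")

# Luminance weights (ITU-R 601, as used by skimage's rgb2gray).
_LUM = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class TransformSpec:
    """One evaluation-time image transformation.

    kind: rotation (degrees, normalized to [0, 360)), horizontal_flip
    (no parameter), brightness or contrast (multiplicative factor > 0).
    ``transform_id`` canonically encodes (kind, parameter).
    """

    kind: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rotation":
            if self.parameter is None:
                raise ValueError("rotation needs a degree parameter")
            object.__setattr__(self, "parameter", float(self.parameter) % 360.0)
        elif self.kind == "horizontal_flip":
            if self.parameter is not None:
                raise ValueError("horizontal_flip takes no parameter")
        else:
            if self.parameter is None or self.parameter <= 0:
                raise ValueError(f"{self.kind} factor must be positive")
            object.__setattr__(self, "parameter", float(self.parameter))

    @property
    def transform_id(self) -> str:
        if self.kind == "horizontal_flip":
            return "horizontal_flip"
        return f"{self.kind}:{self.parameter:g}"

    @classmethod
    def from_id(cls, transform_id: str) -> "TransformSpec":
        if transform_id == "horizontal_flip":
            return cls("horizontal_flip")
        kind, _, param = transform_id.partition(":")
        return cls(kind, float(param))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return apply_transform(image, self)


def apply_transform(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply one transformation to an RGB raster; shape and dtype preserved.

    Rotation is about the image center with reflection padding (zero-fill
    would introduce black corners that are themselves artifacts) and
    bilinear interpolation; 0 degrees is an exact passthrough. Brightness
    multiplies all channels by the factor; contrast rescales around the
    per-image mean luminance; both clip to the valid range.
    """
    img = np.asarray(image)
    as_uint8 = img.dtype == np.uint8
    x = img.astype(float) / 255.0 if as_uint8 else img.astype(float)
    if spec.kind == "rotation":
        if spec.parameter == 0.0:
            out = x.copy()
        else:
            out = _sk_rotate(x, spec.parameter, resize=False, order=1,
                             mode="reflect", clip=True)
    elif spec.kind == "horizontal_flip":
        out = x[:, ::-1].copy()
    elif spec.kind == "brightness":
        out = np.clip(x * spec.parameter, 0.0, 1.0)
    else:  # contrast
        mean_lum = float((x @ _LUM).mean()) if x.ndim == 3 else float(x.mean())
        out = np.clip(mean_lum + spec.parameter * (x - mean_lum), 0.0, 1.0)
    if as_uint8:
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return out


def default_battery() -> list[TransformSpec]:
    """Symmetric default sweep: 45-degree rotations, flip, mild B/C factors."""
    specs = [TransformSpec("rotation", d) for d in range(45, 360, 45)]
    specs.append(TransformSpec("horizontal_flip"))
    specs += [TransformSpec("brightness", f) for f in (0.8, 1.2)]
    specs += [TransformSpec("contrast", f) for f in (0.8, 1.2)]
    return specs


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

ROBUSTNESS_CATEGORIES = (
    "consistently_correct",
    "consistently_wrong",
    "correct_original_wrong_transformed",
    "wrong_original_correct_transformed",
)

REPLICATE_CATEGORIES = ("all_correct", "all_wrong", "mixed")


@dataclass(frozen=True)
class RobustnessVerdict:
    lesion_id: str
    category: str
    flipping_transforms: tuple[str, ...]  # transform_ids that changed the call
    max_abs_change: float


@dataclass(frozen=True)
class SweepResult:
    verdicts: list[RobustnessVerdict]
    median_abs_change: float
    iqr_abs_change: float
    abs_changes: np.ndarray  # pooled per-(image, transform) |delta p|
    non_robust_fraction: float
    predictions: PredictionSet  # raw per-(image, transform) table
    category_counts: dict[str, int] = field(default_factory=dict)


def _correct_call(p: float, truth_pos: bool, threshold: float) -> bool:
    return (p > threshold) == truth_pos


def categorize_sweep(
    pset: PredictionSet, threshold: OperatingPoint | float
) -> SweepResult:
    """Assign the four-way robustness verdict per lesion from a sweep table.

    ``pset`` holds, per image, the original prediction (transform_id None)
    and one record per transformed copy. Lesions lacking an original are
    skipped with a warning. The non-robust fraction is the share of
    evaluated lesions in the two flip categories.
    """
    t = threshold.threshold if isinstance(threshold, OperatingPoint) else float(threshold)
    sub = pset.filter(include_ood=False)
    # lesion -> image -> {transform_id: p}
    per_lesion: dict[str, dict[str, dict[str | None, float]]] = {}
    for rec, p in zip(sub.records, sub.positive_scores()):
        m = sub.manifest[rec.image_id]
        per_lesion.setdefault(m.lesion_id, {}).setdefault(rec.image_id, {})[
            rec.transform_id
        ] = float(p)
    verdicts = []
    changes: list[float] = []
    for lesion_id in sorted(per_lesion):
        images = per_lesion[lesion_id]
        if any(None not in preds for preds in images.values()):
            logger.warning("lesion %s missing an original prediction; skipped",
                           lesion_id)
            continue
        truth_pos = (
            sub.manifest[next(iter(images))].true_label == sub.positive_class
        )
        orig_correct: list[bool] = []
        trans_correct: list[bool] = []
        flipping: set[str] = set()
        max_change = 0.0
        for image_id, preds in images.items():
            p0 = preds[None]
            oc = _correct_call(p0, truth_pos, t)
            orig_correct.append(oc)
            for tid, p in preds.items():
                if tid is None:
                    continue
                changes.append(abs(p - p0))
                max_change = max(max_change, abs(p - p0))
                tc = _correct_call(p, truth_pos, t)
                trans_correct.append(tc)
                if tc != oc:
                    flipping.add(tid)
        all_preds = orig_correct + trans_correct
        if all(all_preds):
            cat = "consistently_correct"
        elif not any(all_preds):
            cat = "consistently_wrong"
        elif all(orig_correct):
            cat = "correct_original_wrong_transformed"
        else:
            cat = "wrong_original_correct_transformed"
        verdicts.append(
            RobustnessVerdict(lesion_id, cat, tuple(sorted(flipping)), max_change)
        )
    counts = {c: sum(v.category == c for v in verdicts) for c in ROBUSTNESS_CATEGORIES}
    n = len(verdicts)
    non_robust = (
        (counts["correct_original_wrong_transformed"]
         + counts["wrong_original_correct_transformed"]) / n if n else float("nan")
    )
    arr = np.asarray(changes, dtype=float)
    med = float(np.median(arr)) if len(arr) else float("nan")
    iqr = float(np.percentile(arr, 75) - np.percentile(arr, 25)) if len(arr) else float("nan")
    return SweepResult(verdicts, med, iqr, arr, non_robust, pset, counts)


def transform_sweep(
    predictor: Predictor,
    manifest: Manifest,
    specs: Sequence[TransformSpec],
    threshold: OperatingPoint | float,
    *,
    images: dict[str, np.ndarray] | None = None,
    positive_class: str | None = None,
) -> SweepResult:
    """Predict originals and every transformed copy, then categorize lesions.

    The threshold is fixed before the sweep (typically sensitivity-matched
    to a human benchmark on the untransformed set).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    pset = apply_predictor(
        predictor, manifest, images=images, transforms=list(specs),
        positive_class=positive_class,
    )
    return categorize_sweep(pset, threshold)


@dataclass(frozen=True)
class RotationProfile:
    degrees: tuple[float, ...]
    probabilities: tuple[float, ...]  # positive-class probability per angle
    crosses_threshold: bool


def rotation_profile(
    predictor: Predictor,
    image: np.ndarray,
    threshold: OperatingPoint | float,
    degrees_grid: Sequence[float] | None = None,
    positive_index: int = 0,
) -> RotationProfile:
    """Positive-class probability as the image rotates through a grid.

    An image is flagged non-robust when the trace crosses the decision
    threshold — i.e. the diagnosis depends on how the photograph happened
    to be oriented. Default grid: every 15 degrees in [0, 360).
    """
    if degrees_grid is None:
        degrees_grid = list(range(0, 360, 15))
    degrees = [float(d) for d in degrees_grid]
    if not degrees:
        raise ValueError("degrees grid is empty")
    t = threshold.threshold if isinstance(threshold, OperatingPoint) else float(threshold)
    probs = []
    for d in degrees:
        out = np.asarray(
            predictor(apply_transform(image, TransformSpec("rotation", d))),
            dtype=float,
        )
        probs.append(float(out[positive_index]))
    above = [p > t for p in probs]
    return RotationProfile(tuple(degrees), tuple(probs),
                           crosses_threshold=any(above) and not all(above))


@dataclass(frozen=True)
class ReplicateVerdict:
    lesion_id: str
    category: str
    image_probs: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class ReplicateResult:
    verdicts: list[ReplicateVerdict]
    category_counts: dict[str, int]
    category_percentages: dict[str, float]
    n_single_image_lesions: int


def replicate_consistency(
    pset: PredictionSet, threshold: OperatingPoint | float
) -> ReplicateResult:
    """Classify each multi-image lesion as all_correct / all_wrong / mixed.

    Only original (untransformed) predictions participate. Lesions with a
    single image cannot be inconsistent and are excluded but counted.
    """
    t = threshold.threshold if isinstance(threshold, OperatingPoint) else float(threshold)
    sub = pset.filter(originals_only=True, include_ood=False)
    per_lesion: dict[str, list[tuple[str, float, bool]]] = {}
    for rec, p in zip(sub.records, sub.positive_scores()):
        m = sub.manifest[rec.image_id]
        truth_pos = m.true_label == sub.positive_class
        per_lesion.setdefault(m.lesion_id, []).append(
            (rec.image_id, float(p), truth_pos)
        )
    verdicts = []
    singles = 0
    for lesion_id in sorted(per_lesion):
        entries = per_lesion[lesion_id]
        if len(entries) < 2:
            singles += 1
            continue
        correct = [_correct_call(p, truth, t) for _, p, truth in entries]
        if all(correct):
            cat = "all_correct"
        elif not any(correct):
            cat = "all_wrong"
        else:
            cat = "mixed"
        verdicts.append(
            ReplicateVerdict(
                lesion_id, cat, tuple((i, p) for i, p, _ in entries)
            )
        )
    if not verdicts:
        logger.warning("no lesions with >= 2 images; empty replicate result")
    counts = {c: sum(v.category == c for v in verdicts) for c in REPLICATE_CATEGORIES}
    n = len(verdicts)
    pct = {c: (100.0 * k / n if n else float("nan")) for c, k in counts.items()}
    return ReplicateResult(verdicts, counts, pct, singles)


def test_time_augmentation(
    predictor: Predictor,
    image: np.ndarray,
    specs: Sequence[TransformSpec],
    *,
    include_original: bool = True,
) -> np.ndarray:
    """Average the predictor over the original plus its transformed copies."""
    if not specs and not include_original:
        raise ValueError("specs must be non-empty")
    outs = []
    if include_original:
        outs.append(np.asarray(predictor(image), dtype=float))
    for spec in specs:
        outs.append(np.asarray(predictor(apply_transform(image, spec)), dtype=float))
    if not outs:
        raise ValueError("nothing to average")
    mean = np.mean(outs, axis=0)
    return mean / mean.sum()


test_time_augmentation.__test__ = False  # not a pytest case despite the name
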