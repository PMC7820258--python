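"""Core data model: image manifests, prediction sets, rater tables and I/O.

The unit everything downstream consumes is a :class:`PredictionSet` — one
model's class-probability vectors over the images of a manifest. Manifests
and score tables are plain CSV (JSON accepted as an alternate serialization
of the same schema), so prediction tables from any trainer can be audited.

Conventions
-----------
* Class names are an ordered tuple with an explicit positive class
  (melanoma in the dermatology setting); the positive class is required
  configuration, never inferred, to avoid silent sign flips in
  sensitivity/threshold logic.
* Confidence of a prediction is the maximum class probability
  (binary case: ``max(p, 1 - p)``).
* Records whose true label falls outside the declared class set are
  flagged out-of-distribution (OOD) and excluded from discrimination
  metrics unless an operation says otherwise.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import (
    AlignmentError,
    ContractError,
    DanglingReferenceError,
    SchemaError,
    ValidationError,
)

SPLITS = ("train", "validation", "test")

_PROB_ATOL = 1e-9
_PREDICTOR_ATOL = 1e-6

MANIFEST_COLUMNS = ("image_id", "lesion_id", "dataset_id", "split", "true_label")


@dataclass(frozen=True)
class ImageRecord:
    """One image's identity, grouping keys and ground truth.

    ``lesion_id`` is the replicate-group key: multiple photographs of the
    same lesion taken during one visit share it. ``is_ood`` marks classes
    outside the declared training label set (e.g. actinic or seborrheic
    keratoses for a melanoma/nevus model).
    """

    image_id: str
    lesion_id: str
    dataset_id: str
    split: str
    true_label: str
    path: str | None = None
    is_ood: bool = False

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValidationError(
                f"image {self.image_id!r}: split {self.split!r} not in {SPLITS}"
            )


class Manifest:
    """Validated collection of :class:`ImageRecord` with a declared class set."""

    def __init__(self, records: Iterable[ImageRecord], class_names: Sequence[str]):
        self.class_names: tuple[str, ...] = tuple(class_names)
        if len(self.class_names) < 2:
            raise ValidationError("at least two class names are required")
        self.records: list[ImageRecord] = list(records)
        seen: dict[str, int] = {}
        dups = []
        for rec in self.records:
            if rec.image_id in seen:
                dups.append(rec.image_id)
            seen[rec.image_id] = seen.get(rec.image_id, 0) + 1
        if dups:
            raise ValidationError(f"duplicate image_id values: {sorted(set(dups))}")
        # OOD flag must agree with class membership
        fixed = []
        for rec in self.records:
            ood = rec.true_label not in self.class_names
            fixed.append(replace(rec, is_ood=ood) if rec.is_ood != ood else rec)
        self.records = fixed
        self._by_id = {rec.image_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def __getitem__(self, image_id: str) -> ImageRecord:
        try:
            return self._by_id[image_id]
        except KeyError:
            raise DanglingReferenceError(f"unknown image_id {image_id!r}") from None

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._by_id

    def subset(
        self,
        *,
        split: str | None = None,
        include_ood: bool = True,
        dataset_id: str | None = None,
    ) -> "Manifest":
        recs = [
            r
            for r in self.records
            if (split is None or r.split == split)
            and (include_ood or not r.is_ood)
            and (dataset_id is None or r.dataset_id == dataset_id)
        ]
        return Manifest(recs, self.class_names)

    def lesion_groups(self) -> dict[str, list[ImageRecord]]:
        """Records grouped by lesion_id (replicated images share one key)."""
        groups: dict[str, list[ImageRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.lesion_id, []).append(rec)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "lesion_id": [r.lesion_id for r in self.records],
                "dataset_id": [r.dataset_id for r in self.records],
                "split": [r.split for r in self.records],
                "true_label": [r.true_label for r in self.records],
                "path": [r.path if r.path is not None else "" for r in self.records],
            }
        )


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction: probability vector over the declared classes.

    ``transform_id`` identifies which transformed copy of the image the
    prediction was made on; ``None`` means the original image. ``probs``
    must be a distribution; when ``logits`` are present they must agree
    with ``probs`` under softmax (tolerance 1e-9).
    """

    image_id: str
    probs: tuple[float, ...]
    logits: tuple[float, ...] | None = None
    transform_id: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", tuple(float(x) for x in p))
        if np.any(p < -_PROB_ATOL) or np.any(p > 1 + _PROB_ATOL):
            raise ValidationError(f"{self.image_id}: probabilities outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > _PROB_ATOL:
            raise ValidationError(
                f"{self.image_id}: probabilities sum to {p.sum():.12f}, not 1"
            )
        if self.logits is not None:
            z = np.asarray(self.logits, dtype=float)
            object.__setattr__(self, "logits", tuple(float(x) for x in z))
            if z.shape != p.shape:
                raise ValidationError(f"{self.image_id}: logits/probs length mismatch")
            if np.max(np.abs(softmax(z) - p)) > 1e-9:
                raise ValidationError(
                    f"{self.image_id}: probs are not softmax(logits) within 1e-9"
                )

    @property
    def confidence(self) -> float:
        return max(self.probs)

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.image_id, self.transform_id)


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class PredictionSet:
    """Predictions of one (model, dataset, split), resolved against a manifest."""

    def __init__(
        self,
        records: Iterable[PredictionRecord],
        manifest: Manifest,
        positive_class: str | None = None,
    ):
        self.records: list[PredictionRecord] = list(records)
        self.manifest = manifest
        if positive_class is None:
            positive_class = manifest.class_names[0]
        if positive_class not in manifest.class_names:
            raise ValidationError(
                f"positive class {positive_class!r} not in {manifest.class_names}"
            )
        self.positive_class = positive_class
        seen: set[tuple[str, str | None]] = set()
        for rec in self.records:
            if rec.image_id not in manifest:
                raise DanglingReferenceError(
                    f"prediction references unknown image_id {rec.image_id!r}"
                )
            if len(rec.probs) != len(manifest.class_names):
                raise ValidationError(
                    f"{rec.image_id}: {len(rec.probs)} probabilities for "
                    f"{len(manifest.class_names)} classes"
                )
            if rec.key in seen:
                raise ValidationError(f"duplicate (image_id, transform) key {rec.key}")
            seen.add(rec.key)

    # -- array views ------------------------------------------------------
    @property
    def class_names(self) -> tuple[str, ...]:
        return self.manifest.class_names

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PredictionRecord]:
        return iter(self.records)

    def probs_matrix(self) -> np.ndarray:
        return np.asarray([rec.probs for rec in self.records], dtype=float)

    def prob_of(self, class_name: str) -> np.ndarray:
        idx = self.class_names.index(class_name)
        return self.probs_matrix()[:, idx]

    def positive_scores(self) -> np.ndarray:
        """Probability of the positive class, per record."""
        return self.prob_of(self.positive_class)

    def confidences(self) -> np.ndarray:
        return self.probs_matrix().max(axis=1)

    def true_labels(self) -> list[str]:
        return [self.manifest[rec.image_id].true_label for rec in self.records]

    def y_true(self) -> np.ndarray:
        """Binary indicator of the positive class; OOD records get -1."""
        out = np.empty(len(self.records), dtype=int)
        for i, rec in enumerate(self.records):
            m = self.manifest[rec.image_id]
            out[i] = -1 if m.is_ood else int(m.true_label == self.positive_class)
        return out

    def predicted_labels(self) -> list[str]:
        names = self.class_names
        return [names[int(np.argmax(rec.probs))] for rec in self.records]

    def correct(self) -> np.ndarray:
        """Argmax-class correctness per record (OOD records are never correct)."""
        truth = self.true_labels()
        return np.asarray(
            [p == t for p, t in zip(self.predicted_labels(), truth)], dtype=bool
        )

    # -- subsetting -------------------------------------------------------
    def filter(
        self,
        *,
        originals_only: bool = False,
        include_ood: bool = True,
        split: str | None = None,
        true_label: str | None = None,
    ) -> "PredictionSet":
        recs = []
        for rec in self.records:
            m = self.manifest[rec.image_id]
            if originals_only and rec.transform_id is not None:
                continue
            if not include_ood and m.is_ood:
                continue
            if split is not None and m.split != split:
                continue
            if true_label is not None and m.true_label != true_label:
                continue
            recs.append(rec)
        return PredictionSet(recs, self.manifest, self.positive_class)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list] = {
            "image_id": [r.image_id for r in self.records],
            "transform_id": [
                r.transform_id if r.transform_id is not None else ""
                for r in self.records
            ],
        }
        P = self.probs_matrix()
        for j, name in enumerate(self.class_names):
            data[f"prob_{name}"] = list(P[:, j])
        if all(r.logits is not None for r in self.records) and self.records:
            Z = np.asarray([r.logits for r in self.records], dtype=float)
            for j, name in enumerate(self.class_names):
                data[f"logit_{name}"] = list(Z[:, j])
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Manifest / score-table I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_manifest(path: str | Path, class_names: Sequence[str]) -> Manifest:
    """Read an image manifest (CSV or JSON) and validate it.

    Required columns: image_id, lesion_id, dataset_id, split, true_label.
    Optional: path. OOD flags are derived from ``class_names`` membership.
    """
    df = _read_table(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path}: missing column(s) {missing}")
    base = Path(path).parent

    def _resolve(p: str) -> str | None:
        if not p:
            return None
        # relative image paths are taken relative to the manifest file
        return p if Path(p).is_absolute() else str(base / p)

    records = [
        ImageRecord(
            image_id=str(row.image_id),
            lesion_id=str(row.lesion_id),
            dataset_id=str(row.dataset_id),
            split=str(row.split),
            true_label=str(row.true_label),
            path=_resolve(str(row.path)) if "path" in df.columns else None,
        )
        for row in df.itertuples()
    ]
    return Manifest(records, class_names)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    df = manifest.to_frame()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def read_scores(
    path: str | Path,
    manifest: Manifest,
    positive_class: str | None = None,
) -> PredictionSet:
    """Read a score table (CSV or JSON) into a :class:`PredictionSet`.

    The table carries ``image_id`` (plus optional ``transform_id``) and
    either ``prob_<class>`` or ``logit_<class>`` columns per declared class;
    when only logits are given, probabilities are their softmax.
    """
    df = _read_table(path)
    if "image_id" not in df.columns:
        raise SchemaError(f"score table {path}: missing column 'image_id'")
    names = manifest.class_names
    prob_cols = [f"prob_{c}" for c in names]
    logit_cols = [f"logit_{c}" for c in names]
    have_probs = all(c in df.columns for c in prob_cols)
    have_logits = all(c in df.columns for c in logit_cols)
    if not have_probs and not have_logits:
        raise SchemaError(
            f"score table {path}: needs all of {prob_cols} or all of {logit_cols}"
        )
    records = []
    for _, row in df.iterrows():
        tid = str(row["transform_id"]) if "transform_id" in df.columns else ""
        tid = tid or None
        logits = (
            tuple(float(row[c]) for c in logit_cols) if have_logits else None
        )
        if have_probs:
            probs = tuple(float(row[c]) for c in prob_cols)
            if logits is not None and np.max(
                np.abs(softmax(np.array(logits)) - np.array(probs))
            ) > 1e-6:
                raise ValidationError(
                    f"{row['image_id']}: prob columns disagree with logit columns"
                )
        else:
            probs = tuple(softmax(np.array(logits)))
        records.append(
            PredictionRecord(
                image_id=str(row["image_id"]),
                probs=probs,
                logits=logits,
                transform_id=tid,
            )
        )
    return PredictionSet(records, manifest, positive_class)


def write_scores(pset: PredictionSet, path: str | Path) -> None:
    path = Path(path)
    df = pset.to_frame()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Ensembling and the predictor contract
# ---------------------------------------------------------------------------


def ensemble_average(member_sets: Sequence[PredictionSet]) -> PredictionSet:
    """Average the probability vectors of cross-validation ensemble members.

    All members must cover identical (image_id, transform) keys with the
    same class order; per key the output is the arithmetic mean of member
    probabilities (which is again a distribution). Logits are dropped —
    a mean of probabilities has no canonical logit.
    """
    if not member_sets:
        raise AlignmentError("no ensemble members given")
    ref = member_sets[0]
    ref_keys = {r.key for r in ref.records}
    for i, m in enumerate(member_sets[1:], start=2):
        if m.class_names != ref.class_names:
            raise AlignmentError(f"member {i}: class order differs")
        keys = {r.key for r in m.records}
        if keys != ref_keys:
            missing = sorted(k for k, _ in (ref_keys ^ keys))
            raise AlignmentError(f"member {i}: mismatched keys (e.g. {missing[:5]})")
    by_key = [{r.key: np.asarray(r.probs) for r in m.records} for m in member_sets]
    out = []
    for rec in ref.records:
        mean = np.mean([d[rec.key] for d in by_key], axis=0)
        mean = mean / mean.sum()  # renormalize away float drift
        out.append(
            PredictionRecord(rec.image_id, tuple(mean), transform_id=rec.transform_id)
        )
    return PredictionSet(out, ref.manifest, ref.positive_class)


Predictor = Callable[[np.ndarray], Sequence[float]]


def apply_predictor(
    predictor: Predictor,
    manifest: Manifest,
    *,
    images: dict[str, np.ndarray] | None = None,
    transforms: Sequence | None = None,
    positive_class: str | None = None,
) -> PredictionSet:
    """Run a black-box image→probability predictor over a manifest.

    The predictor maps an RGB uint8 array to a probability vector over the
    declared classes; each output is validated (length, range, sum within
    1e-6). The predictor is invoked exactly once per (image, transform)
    pair and results are emitted in manifest order (originals first per
    image, then transforms in the given order).

    ``images`` supplies in-memory arrays keyed by image_id; records without
    an entry are loaded from their ``path``. ``transforms`` is an optional
    list of :class:`~dermastress.robustness.TransformSpec`.
    """
    n_classes = len(manifest.class_names)
    records = []
    for rec in manifest:
        if images is not None and rec.image_id in images:
            img = images[rec.image_id]
        elif rec.path:
            img = load_image(rec.path)
        else:
            raise ContractError(f"{rec.image_id}: no image array and no path")
        variants: list[tuple[str | None, np.ndarray]] = [(None, img)]
        for spec in transforms or ():
            variants.append((spec.transform_id, spec(img)))
        for tid, arr in variants:
            out = np.asarray(predictor(arr), dtype=float)
            if out.shape != (n_classes,):
                raise ContractError(
                    f"{rec.image_id}: predictor returned shape {out.shape}, "
                    f"expected ({n_classes},)"
                )
            if np.any(out < -_PREDICTOR_ATOL) or abs(out.sum() - 1) > _PREDICTOR_ATOL:
                raise ContractError(
                    f"{rec.image_id}: predictor output is not a distribution: {out}"
                )
            out = np.clip(out, 0, None)
            out = out / out.sum()
            records.append(PredictionRecord(rec.image_id, tuple(out), transform_id=tid))
    return PredictionSet(records, manifest, positive_class)


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as 8-bit RGB; grayscale is replicated across channels."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Rater tables
# ---------------------------------------------------------------------------


@dataclass
class RaterTable:
    """Per-rater binary management decisions (biopsy=1 vs reassure=0).

    ``decisions`` has columns rater_id, image_id, decision (0/1) and an
    optional diagnosis column; ``metadata`` maps rater_id to free-form
    attributes (experience band, practice setting).
    """

    decisions: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"rater_id", "image_id", "decision"}
        missing = required - set(self.decisions.columns)
        if missing:
            raise SchemaError(f"rater table: missing column(s) {sorted(missing)}")
        dup = self.decisions.duplicated(subset=["rater_id", "image_id"])
        if dup.any():
            bad = self.decisions.loc[dup, ["rater_id", "image_id"]]
            raise ValidationError(
                f"rater decided an image more than once: {bad.values.tolist()[:5]}"
            )
        vals = set(pd.unique(self.decisions["decision"]))
        if not vals <= {0, 1, "0", "1", True, False}:
            raise ValidationError(f"decisions must be binary 0/1, got {vals}")
        self.decisions = self.decisions.assign(
            decision=self.decisions["decision"].astype(int)
        )

    def validate_against(self, manifest: Manifest) -> None:
        unknown = [i for i in self.decisions["image_id"] if i not in manifest]
        if unknown:
            raise DanglingReferenceError(
                f"rater decisions reference unknown image_ids: {sorted(set(unknown))[:5]}"
            )

    def rater_ids(self) -> list[str]:
        return sorted(map(str, pd.unique(self.decisions["rater_id"])))


def read_rater_table(path: str | Path) -> RaterTable:
    return RaterTable(_read_table(path))


def write_rater_table(table: RaterTable, path: str | Path) -> None:
    table.decisions.to_csv(path, index=False)
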