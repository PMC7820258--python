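"""Deterministic synthetic fixtures: lesion-like images, score tables, raters.

Everything downstream of the stress battery is exercised on procedurally
rendered images — no patient data, no downloads. The corpus emulates the
*structure* of a dermatology evaluation set: two in-distribution classes
(melanoma, nevus) at roughly 1:2 imbalance, lesions photographed one to a
few times per visit (replicates sharing a lesion_id), and optional
out-of-distribution classes rendered from distinct parametric families
(actinic keratosis: rough pink patch; seborrheic keratosis: stippled,
sharply bounded waxy plaque).

A melanoma here is an irregular, asymmetric, dark and color-variegated
blob; a nevus is a rounder, more uniform one. A single class-separation
parameter ``delta`` scales every class-dependent difference: at delta = 0
the two class-conditional image distributions are identical (no
classifier can beat chance), and classification gets monotonically easier
as delta grows. That gives the test suite a knob whose ground truth is
known by construction.

The toy classifier is a multinomial logistic model over fixed, hand-
crafted image features (color, darkness, asymmetry, border irregularity,
variegation). It is deliberately *not* a CNN and makes no claim of
clinical-grade discrimination; its job is to be a fast, deterministic,
contract-satisfying predictor for the stress battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.optimize import minimize
from scipy.special import expit, logit as _logit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .data import (
    ImageRecord,
    Manifest,
    PredictionRecord,
    PredictionSet,
    RaterTable,
    softmax,
)
from .errors import ContractError
from .selective import DEFAULT_PAYOFF, GamblerBatch

CLASS_NAMES = ("melanoma", "nevus")
OOD_FAMILIES = ("actinic_keratosis", "seborrheic_keratosis")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one corpus; same (seed, config) => same bytes."""

    seed: int = 0
    n_lesions: dict[str, int] = field(
        default_factory=lambda: {"melanoma": 15, "nevus": 30}
    )
    images_per_lesion: tuple[int, int] = (1, 3)
    image_size: int = 64
    delta: float = 2.0  # class separation; 0 = indistinguishable classes
    ood_lesions: dict[str, int] = field(default_factory=dict)
    label_noise: float = 0.0
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    dataset_id: str = "synthetic"
    # replicate jitter: pose rotation sd (deg), center shift sd (fraction),
    # illumination sd (multiplicative)
    jitter_rotation: float = 20.0
    jitter_shift: float = 0.03
    jitter_illumination: float = 0.05

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_lesions.values()):
            raise ValueError("lesion counts must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        lo, hi = self.images_per_lesion
        if not 1 <= lo <= hi:
            raise ValueError("images_per_lesion must be a valid positive range")
        for k in self.ood_lesions:
            if k not in OOD_FAMILIES:
                raise ValueError(f"unknown OOD family {k!r}; known: {OOD_FAMILIES}")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _lesion_params(rng: np.random.Generator, label: str, delta: float) -> dict:
    """Class-conditional lesion parameters; melanoma shifts scale with delta."""
    mel = label == "melanoma"
    d = delta if mel else 0.0
    return {
        "radius": rng.uniform(0.18, 0.26),
        "elongation": 1.0 + rng.uniform(0.0, 0.15) + d * rng.uniform(0.03, 0.08),
        "border_amp": rng.uniform(0.01, 0.04) + d * rng.uniform(0.015, 0.035),
        "border_phases": rng.uniform(0, 2 * np.pi, size=5),
        "border_weights": rng.uniform(0.3, 1.0, size=5),
        "color": np.array([0.46, 0.31, 0.23])
        + rng.normal(0, 0.02, size=3)
        - d * np.array([0.045, 0.035, 0.02]),
        "variegation": 0.015 + d * 0.02,
        "asym_amp": d * rng.uniform(0.02, 0.05),
        "asym_phase": rng.uniform(0, 2 * np.pi),
        "skin": np.array([0.80, 0.62, 0.55]) + rng.normal(0, 0.015, size=3),
        "texture_seed": int(rng.integers(0, 2**31 - 1)),
    }


def _ood_params(rng: np.random.Generator, family: str) -> dict:
    if family == "actinic_keratosis":
        return {
            "radius": rng.uniform(0.22, 0.32),
            "elongation": 1.0 + rng.uniform(0.0, 0.3),
            "border_amp": rng.uniform(0.06, 0.12),  # diffuse, scaly margin
            "border_phases": rng.uniform(0, 2 * np.pi, size=5),
            "border_weights": rng.uniform(0.3, 1.0, size=5),
            "color": np.array([0.72, 0.45, 0.40]) + rng.normal(0, 0.02, size=3),
            "variegation": 0.05,  # rough, high-frequency surface
            "asym_amp": rng.uniform(0.0, 0.03),
            "asym_phase": rng.uniform(0, 2 * np.pi),
            "skin": np.array([0.80, 0.62, 0.55]) + rng.normal(0, 0.015, size=3),
            "texture_seed": int(rng.integers(0, 2**31 - 1)),
        }
    # seborrheic keratosis: round, sharply bounded, stippled light brown
    return {
        "radius": rng.uniform(0.20, 0.30),
        "elongation": 1.0 + rng.uniform(0.0, 0.08),
        "border_amp": rng.uniform(0.0, 0.015),
        "border_phases": rng.uniform(0, 2 * np.pi, size=5),
        "border_weights": rng.uniform(0.3, 1.0, size=5),
        "color": np.array([0.55, 0.40, 0.28]) + rng.normal(0, 0.02, size=3),
        "variegation": 0.035,
        "asym_amp": rng.uniform(0.0, 0.02),
        "asym_phase": rng.uniform(0, 2 * np.pi),
        "skin": np.array([0.80, 0.62, 0.55]) + rng.normal(0, 0.015, size=3),
        "texture_seed": int(rng.integers(0, 2**31 - 1)),
    }


def render_lesion(
    params: dict,
    size: int,
    *,
    pose_deg: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
    illumination: float = 1.0,
    noise_seed: int = 0,
) -> np.ndarray:
    """Render one lesion image (uint8 RGB) from its parameter dict.

    The lesion boundary is a star-shaped radial function
    r(theta) = r0 * (1 + asym*sin(theta+phi) + amp * sum_k w_k sin(k theta + phi_k))
    stretched by the elongation ratio, anti-aliased with a soft edge.
    """
    rng = np.random.default_rng(noise_seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + shift[0] * size
    cy = size / 2 + shift[1] * size
    x = (xx - cx) / size
    y = (yy - cy) / size
    # pose rotation of the lesion shape (replicates vary pose, not content)
    a = np.deg2rad(pose_deg)
    xr = np.cos(a) * x + np.sin(a) * y
    yr = -np.sin(a) * x + np.cos(a) * y
    xr = xr * params["elongation"]
    theta = np.arctan2(yr, xr)
    rad = np.hypot(xr, yr)
    boundary = params["radius"] * (
        1.0
        + params["asym_amp"] * np.sin(theta + params["asym_phase"])
        + params["border_amp"]
        * sum(
            w * np.sin((k + 2) * theta + ph)
            for k, (w, ph) in enumerate(
                zip(params["border_weights"], params["border_phases"])
            )
        )
    )
    edge_width = 1.5 / size
    inside = np.clip((boundary - rad) / edge_width, 0.0, 1.0)  # soft mask
    img = np.empty((size, size, 3), dtype=float)
    skin = params["skin"]
    lesion = params["color"]
    # smooth illumination gradient across the frame plus pixel noise
    grad = 1.0 + 0.06 * (x + y)
    tex = rng.normal(0.0, params["variegation"], size=(size, size, 1))
    fine = rng.normal(0.0, 0.008, size=(size, size, 3))
    for c in range(3):
        img[..., c] = skin[c] * (1 - inside) + lesion[c] * inside
    img += inside[..., None] * tex
    img = (img + fine) * grad[..., None] * illumination
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def _assign_split(
    rng: np.random.Generator, fractions: tuple[float, float, float]
) -> str:
    u = rng.random()
    if u < fractions[0]:
        return "train"
    if u < fractions[0] + fractions[1]:
        return "validation"
    return "test"


def generate_image_corpus(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[Manifest, dict[str, np.ndarray]]:
    """Render a full corpus: manifest plus in-memory uint8 RGB arrays.

    Each lesion is rendered 1..k times with small pose/illumination jitter
    (the replicates); split assignment is per lesion so replicates never
    straddle splits. With ``out_dir`` the images are also written as PNG
    and the manifest rows carry their paths.
    """
    root = np.random.SeedSequence(config.seed)
    records: list[ImageRecord] = []
    images: dict[str, np.ndarray] = {}
    families = [(lbl, n, False) for lbl, n in sorted(config.n_lesions.items())]
    families += [(lbl, n, True) for lbl, n in sorted(config.ood_lesions.items())]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    lesion_counter = 0
    for label, n, is_ood in families:
        for _ in range(n):
            lesion_counter += 1
            lesion_id = f"L{lesion_counter:04d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            params = (
                _ood_params(rng, label) if is_ood
                else _lesion_params(rng, label, config.delta)
            )
            split = "test" if is_ood else _assign_split(rng, config.split_fractions)
            recorded = label
            if not is_ood and config.label_noise > 0 and rng.random() < config.label_noise:
                recorded = next(c for c in config.n_lesions if c != label)
            lo, hi = config.images_per_lesion
            n_img = int(rng.integers(lo, hi + 1))
            for j in range(n_img):
                image_id = f"{lesion_id}_img{j}"
                img = render_lesion(
                    params,
                    config.image_size,
                    pose_deg=float(rng.normal(0, config.jitter_rotation)) if j else 0.0,
                    shift=tuple(rng.normal(0, config.jitter_shift, size=2)) if j else (0.0, 0.0),
                    illumination=float(
                        np.exp(rng.normal(0, config.jitter_illumination))
                    ) if j else 1.0,
                    noise_seed=int(rng.integers(0, 2**31 - 1)),
                )
                images[image_id] = img
                path = None
                if out_path is not None:
                    path = str(out_path / f"{image_id}.png")
                    Image.fromarray(img).save(path)
                records.append(
                    ImageRecord(
                        image_id=image_id,
                        lesion_id=lesion_id,
                        dataset_id=config.dataset_id,
                        split=split,
                        true_label=recorded,
                        path=path,
                    )
                )
    return Manifest(records, CLASS_NAMES), images


# ---------------------------------------------------------------------------
# Scored-prediction generator (known temperature, known AUROC)
# ---------------------------------------------------------------------------


def generate_scored_predictions(
    n: int,
    true_temperature: float,
    base_auroc: float,
    seed: int,
    *,
    prevalence: float = 0.35,
    class_names: Sequence[str] = CLASS_NAMES,
    split: str = "test",
    dataset_id: str = "synthetic-scores",
) -> PredictionSet:
    """Score table whose miscalibration is exactly a known temperature.

    Binormal construction: labels y ~ Bernoulli(prevalence); a latent score
    z ~ N(+mu/2, 1) for positives and N(-mu/2, 1) for negatives, with
    mu = sqrt(2) * Phi^{-1}(base_auroc). The *calibrated* log-odds of the
    positive class is then exactly logit(prevalence) + mu*z. Emitted
    logits are that quantity multiplied by ``true_temperature``, so
    temperature scaling recovers T* and the ranking (hence AUROC) is
    independent of T*.
    """
    if true_temperature <= 0:
        raise ValueError("true_temperature must be positive")
    if not 0.5 <= base_auroc < 1:
        raise ValueError("base_auroc must be in [0.5, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mu = float(np.sqrt(2.0) * norm.ppf(base_auroc))
    y = rng.random(n) < prevalence
    z = rng.normal(0.0, 1.0, size=n) + np.where(y, mu / 2.0, -mu / 2.0)
    cal_logit = _logit(prevalence) + mu * z
    emitted = true_temperature * cal_logit
    pos, neg = class_names[0], class_names[1]
    records = []
    manifest_rows = []
    for i in range(n):
        iid = f"S{i:05d}"
        logits = (float(emitted[i]), 0.0)
        probs = tuple(softmax(np.array(logits)))
        records.append(PredictionRecord(iid, probs, logits=logits))
        manifest_rows.append(
            ImageRecord(iid, iid, dataset_id, split, pos if y[i] else neg)
        )
    manifest = Manifest(manifest_rows, tuple(class_names))
    return PredictionSet(records, manifest, positive_class=pos)


# ---------------------------------------------------------------------------
# Rater tables
# ---------------------------------------------------------------------------


def generate_rater_table(
    manifest: Manifest,
    n_raters: int,
    sensitivity: float | Sequence[float],
    specificity: float | Sequence[float],
    seed: int,
    positive_class: str = "melanoma",
) -> RaterTable:
    """Simulated binary management decisions at stated per-rater rates.

    Conditional on truth, each decision is an independent Bernoulli draw:
    a rater with sensitivity s biopsies a true positive with probability s
    and a true negative with probability 1 - specificity. OOD images are
    not shown to raters.
    """
    sens = np.broadcast_to(np.asarray(sensitivity, dtype=float), (n_raters,))
    spec = np.broadcast_to(np.asarray(specificity, dtype=float), (n_raters,))
    if np.any((sens < 0) | (sens > 1) | (spec < 0) | (spec > 1)):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_raters):
        rid = f"rater{r + 1:02d}"
        for rec in manifest:
            if rec.is_ood:
                continue
            truth_pos = rec.true_label == positive_class
            p_biopsy = sens[r] if truth_pos else 1.0 - spec[r]
            rows.append(
                {
                    "rater_id": rid,
                    "image_id": rec.image_id,
                    "decision": int(rng.random() < p_biopsy),
                }
            )
    return RaterTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Toy classifier
# ---------------------------------------------------------------------------


def image_features(img: np.ndarray) -> np.ndarray:
    """Fixed interpretable features: color, darkness, asymmetry, border, texture."""
    x = img.astype(float) / 255.0 if img.dtype == np.uint8 else np.asarray(img, float)
    lum = x @ np.array([0.2125, 0.7154, 0.0721])
    dark_cut = np.quantile(lum, 0.25)
    dark = lum <= dark_cut
    gy, gx = np.gradient(lum)
    grad = np.hypot(gx, gy)
    feats = [
        x[..., 0].mean(), x[..., 1].mean(), x[..., 2].mean(),
        lum.std(),
        lum[dark].mean(),                       # darkness of the lesion core
        np.abs(lum - lum[:, ::-1]).mean(),      # left-right asymmetry
        np.abs(lum - lum[::-1, :]).mean(),      # top-bottom asymmetry
        grad.mean(),                            # border irregularity proxy
        (x[..., 0] - x[..., 2])[dark].std(),    # color variegation in the core
        dark.mean(),                            # relative lesion area
    ]
    return np.asarray(feats, dtype=float)


class ToyLesionClassifier(BaseEstimator):
    """Deterministic multinomial logistic classifier over fixed image features.

    Supports the standard cross-entropy objective or the gambler's loss
    with an extra reject output (payoff ``o``). Optimized with L-BFGS from
    a zero initialization, so training is seconds-fast on a CPU and fully
    reproducible. Exposes the black-box predictor contract: calling the
    fitted model on one image returns the class-probability vector (the
    gambler variant renormalizes over the real classes).

    Parameters
    ----------
    loss : {"cross_entropy", "gambler"}
    payoff : float
        Gambler payoff o > 1; ignored for cross-entropy.
    l2 : float
        Ridge penalty on the weights (not the intercepts).
    """

    def __init__(
        self,
        loss: str = "cross_entropy",
        payoff: float = DEFAULT_PAYOFF,
        l2: float = 1e-2,
        max_iter: int = 500,
    ):
        self.loss = loss
        self.payoff = payoff
        self.l2 = l2
        self.max_iter = max_iter

    def _check(self) -> None:
        if self.loss not in ("cross_entropy", "gambler"):
            raise ValueError("loss must be 'cross_entropy' or 'gambler'")
        if self.loss == "gambler" and self.payoff <= 1:
            raise ValueError("gambler payoff must exceed 1")

    def fit(
        self,
        images: Sequence[np.ndarray],
        labels: Sequence[str],
        class_names: Sequence[str] = CLASS_NAMES,
    ) -> "ToyLesionClassifier":
        self._check()
        self.class_names_ = tuple(class_names)
        y = np.asarray([self.class_names_.index(t) for t in labels], dtype=int)
        if len(np.unique(y)) < 2:
            raise ContractError("training data must contain both classes")
        X = np.asarray([image_features(im) for im in images])
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_
        n, d = Xs.shape
        k_out = len(self.class_names_) + (1 if self.loss == "gambler" else 0)
        u_extra = 1.0 / self.payoff if self.loss == "gambler" else None

        def objective(w_flat: np.ndarray) -> tuple[float, np.ndarray]:
            W = w_flat.reshape(k_out, d + 1)
            Z = Xs @ W[:, :-1].T + W[:, -1]
            P = softmax(Z)
            U = np.zeros_like(P)
            U[np.arange(n), y] = 1.0
            if u_extra is not None:
                U[:, -1] = u_extra
            q = np.clip((U * P).sum(axis=1), 1e-12, None)
            f = -np.mean(np.log(q)) + 0.5 * self.l2 * np.sum(W[:, :-1] ** 2)
            G = (P - (U * P) / q[:, None]) / n  # d(-log q)/dZ, batch-averaged
            gW = np.empty_like(W)
            gW[:, :-1] = G.T @ Xs + self.l2 * W[:, :-1]
            gW[:, -1] = G.sum(axis=0)
            return f, gW.ravel()

        res = minimize(
            objective,
            np.zeros(k_out * (d + 1)),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self.coef_ = res.x.reshape(k_out, d + 1)
        self.converged_ = bool(res.success)
        self.n_features_in_ = d
        return self

    def _raw_probs(self, images: Sequence[np.ndarray]) -> np.ndarray:
        X = np.asarray([image_features(im) for im in images])
        Xs = (X - self.mean_) / self.scale_
        Z = Xs @ self.coef_[:, :-1].T + self.coef_[:, -1]
        return softmax(Z)

    def predict_proba(self, images: Sequence[np.ndarray]) -> np.ndarray:
        """Class probabilities (n, k); gambler mass renormalized away."""
        P = self._raw_probs(images)
        if self.loss == "gambler":
            cp = P[:, :-1]
            return cp / cp.sum(axis=1, keepdims=True)
        return P

    def gambler_batch(self, images: Sequence[np.ndarray]) -> GamblerBatch:
        if self.loss != "gambler":
            raise ContractError("not a gambler-loss model")
        return GamblerBatch(self._raw_probs(images), payoff=self.payoff)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Predictor contract: one image -> probability vector over classes."""
        return self.predict_proba([image])[0]


def toy_classifier(
    manifest: Manifest,
    images: dict[str, np.ndarray],
    *,
    split: str = "train",
    loss: str = "cross_entropy",
    payoff: float = DEFAULT_PAYOFF,
    **kwargs,
) -> ToyLesionClassifier:
    """Train the toy classifier on one split of a corpus."""
    sub = manifest.subset(split=split, include_ood=False)
    imgs = [images[r.image_id] for r in sub]
    labels = [r.true_label for r in sub]
    clf = ToyLesionClassifier(loss=loss, payoff=payoff, **kwargs)
    return clf.fit(imgs, labels, manifest.class_names)
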