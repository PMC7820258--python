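# Methods

This note records the statistical and numerical conventions the toolkit
commits to, the design choices that were genuinely open, what the
synthetic generator does and does not emulate, and the problem sizes the
bundled checks run at.

## Data model and conventions

A *prediction set* is a collection of per-image class-probability vectors
resolved against a manifest that carries identity (image_id), replicate
grouping (lesion_id), dataset and split labels, and ground truth. Three
conventions are applied uniformly and recorded in every report's
provenance block:

* **Decision rule.** An image is called positive iff its positive-class
  probability is *strictly greater* than the threshold (`p > t`). The
  positive class (melanoma) is explicit configuration, never inferred.
* **Confidence** is the maximum class probability; in the binary case
  `max(p, 1 − p)`, so it lies in [1/2, 1].
* **OOD records** — images whose true label is outside the declared class
  set — are excluded from discrimination and calibration metrics. In the
  OOD audit their "confidence" is the positive-class probability: the
  question being asked is how strongly the model asserts *melanoma* on a
  disease it was never trained on.

Ensembling averages member probability vectors per (image, transform)
key; the mean of distributions is a distribution, and member order is
irrelevant.

## Discrimination

AUROC is the Mann–Whitney concordance probability (ties count half); the
point estimate is computed by scikit-learn and asserted, in tests,
against exhaustive pair enumeration. The confidence interval uses
DeLong's structural-components variance estimator, implemented here with
midranks (O(n log n)): with `V10_i = mean_j ψ(X_i, Y_j)` and
`V01_j = mean_i ψ(X_i, Y_j)`,
`var(AUC) = S10/m + S01/n`, and the normal interval is clipped to [0, 1].
Single-class inputs raise a degenerate-input error rather than returning
a number.

AUPR is the step-wise (non-interpolated) area, i.e. average precision.

**Sensitivity-matched operating points.** To compare a model with a human
benchmark at a comparable miss rate, the toolkit returns the *largest*
threshold whose sensitivity meets the target. Candidate thresholds are
midpoints between consecutive distinct scores plus sentinels beyond both
extremes; since specificity is non-decreasing in the threshold, the
largest qualifying threshold automatically has maximal specificity. With
the strict `p > t` rule, target 1.0 is met strictly below the minimum
positive score and target 0.0 at threshold 1.0.

**Model vs raters.** Each rater's management decisions give one
(sensitivity, specificity) point; the aggregate "rater ROC area" is the
area of the polygon (0,0) → mean rater point → (1,1), i.e.
`(sens̄ + spec̄)/2` — the standard single-operating-point construction,
labeled as such in output. The comparison of per-rater Youden/F1 values
against the model's scalar is a **two-sided one-sample t-test**; a
zero-variance rater sample short-circuits the test (difference reported
exactly, p = 1 when it is zero) rather than inventing a 0/0 convention.

**Statistical tests.** Rank-based tests delegate to scipy: rank-sum
(Mann–Whitney) exact when the combined sample has ≤ 20 values without
cross-sample ties, signed-rank exact for ≤ 25 non-zero differences
without tied magnitudes; normal approximation with tie correction
otherwise. The test suite checks both against exhaustive enumeration
oracles. Significance is declared at p < 0.05.

## Calibration

Temperature scaling fits one scalar `T ∈ [0.05, 20]` minimizing the mean
NLL of `softmax(z/T)` on a validation split, by bounded scalar
minimization on log T (guaranteed termination; the bounds cover all
practical miscalibration). Because T = 1 lies inside the interval, the
fitted NLL can never exceed the unscaled NLL. Division by a positive
scalar is monotone, so calibration never changes an argmax or a pairwise
ranking — AUROC is invariant, which the tests assert to 1e-12.

When a score table ships probabilities but no logits, log-probabilities
may stand in (`allow_probability_logits`). Softmax is shift-invariant but
temperature scaling is not, so this is an approximation; it is opt-in and
warned about.

**RMS calibration error** uses *equal-mass* (adaptive) bins, default 15:
records sorted by confidence are cut at count quantiles, with tied
confidences kept in one bin so the partition is well defined. Equal-mass
binning is robust to the strong skew of post-softmax confidence
distributions. With fewer records than bins the bin count drops to the
record count with a warning. Because the bin scheme is a free choice,
RMSE values are comparable only within a fixed scheme.

**Expected vs observed accuracy.** The observed curve is the test set's
RRA at each coverage; the expected curve is the validation set's RRA at
the *same coverage fraction* (default) or, optionally, at the same
confidence cutoff. An overconfident model shows observed < expected.

## Selective prediction

The RRA curve ranks records by descending confidence — ties broken by
image_id for determinism, and flagged in the output — and reports
`RRA(c) = (# correct among the first ⌈c·n⌉) / ⌈c·n⌉` (an epsilon guards
the ceiling against float round-off at exact grid points). AURRA is the
mean of RRA over the full per-record grid `{k/n}`; the trapezoid value is
also emitted since the quadrature is a free choice. RRA at coverage 1
equals overall accuracy identically.

The gambler's loss `−log(p_true + p_reject/o)` gives an abstention-capable
model its training objective; `o > 1` is required (at `o ≤ 1` rejecting
dominates and the game is degenerate). With zero rejection mass it equals
cross-entropy exactly. The payoff defaults to 2.2 — a mid-range value for
binary tasks in the regime where rejection is used but not free — and the
rejection decision defaults to the reciprocal-payoff rule
`p_reject > 1/o`; both are configuration and logged. Log arguments are
clamped at 1e-12 with a warning.

Boxplot summaries use Tukey's convention: hinges at the quartiles
(linear-interpolation percentiles), whiskers at the most extreme points
within 1.5·IQR of the hinges.

## Robustness

The transform battery defaults to rotations every 45° (reflection
padding, bilinear interpolation; 0° is an exact passthrough and angles
are normalized mod 360), horizontal flip, and brightness/contrast factors
{0.8, 1.2} — mild, symmetric perturbations emulating capture variation
rather than corruption. Contrast rescales around the per-image mean
luminance (ITU-R 601 weights); brightness multiplies all channels; both
clip to the valid range. Reflection padding is used for rotation because
zero-fill would introduce black corners that are themselves artifacts;
the mode is switchable.

A sweep predicts each lesion's original and transformed copies at a
threshold fixed *before* the sweep (typically sensitivity-matched) and
assigns one of four mutually exclusive categories: consistently correct,
consistently wrong, correct-original-wrong-transformed,
wrong-original-correct-transformed. The non-robust fraction is the share
in the two flip categories. |Δp| values are pooled across all (image,
transform) pairs and summarized by median and IQR. Replicate consistency
partitions multi-image lesions into all-correct / all-wrong / mixed;
single-image lesions are excluded and counted. Rotation profiles default
to a 15° grid over [0, 360); an image is flagged when its probability
trace crosses the decision threshold. Test-time augmentation averages the
probability vectors over the original plus transformed copies; no
improvement is asserted anywhere — the comparison is reported, both ways.

## Synthetic fixtures

The generator emulates the *structure* of a dermatology evaluation
corpus, not its photographic content: two in-distribution classes at
~1:2 melanoma:nevus imbalance (15/30 lesions by default), 1–3 replicates
per lesion with pose/illumination jitter, per-lesion split assignment
(replicates never straddle splits), optional OOD families with distinct
parametric appearance, optional label noise, and 64×64 RGB rendering —
small enough that the full battery runs in seconds on one CPU.

A lesion is a star-shaped blob `r(θ) = r0(1 + asym·sin(θ+φ) +
amp·Σ w_k sin(kθ+φ_k))` on a skin-tone background with an illumination
gradient and pixel noise. Every class-dependent parameter shift
(darkness, variegation, asymmetry, border amplitude, elongation) is
multiplied by the separation parameter δ: at δ = 0 the class-conditional
distributions are *identical by construction* (expected AUROC 0.5 for any
classifier), and separability grows monotonically with δ. δ = 5 is the
"well-separated" regime the end-to-end checks use, where the toy
classifier exceeds AUROC 0.95 on held-out images. All randomness flows
from one seed through spawned generators, so a (seed, config) pair yields
byte-identical PNGs across runs.

The score-table generator is binormal: with
`mu = sqrt(2)·Φ⁻¹(AUROC*)`, latent scores are N(±mu/2, 1) by class, so
the *calibrated* positive log-odds is exactly `logit(prev) + mu·z`;
emitted logits are that quantity times T*. The set is therefore
miscalibrated by exactly a known temperature while its ranking (and
AUROC) is independent of T* — the ground truth behind the
parameter-recovery checks.

The toy classifier is multinomial logistic regression (L-BFGS from zero
initialization, ridge 1e-2, deterministic) over ten fixed features:
channel means, luminance spread, dark-core darkness, left-right and
top-bottom asymmetry, gradient energy, core color variegation, and dark
fraction. The gambler variant adds a third softmax output trained under
the gambler's loss. It is a test harness for the battery, not a clinical
claim.

**What passing tests do not show.** Synthetic blobs have none of the
photographic nuisances of real dermatology data (hair, ink markings,
rulers, glare, skin-tone diversity, focus/exposure failure), the toy
features are nothing like CNN representations, and simulated raters are
Bernoulli machines with constant operating points. Green checks certify
the *metrics and procedures* — not any real model's clinic readiness.

## Problem sizes and numerical choices

The bundled checks run at deliberately small scale: temperature recovery
at n = 2000 with T* ∈ {0.5, 1, 2, 4} (10% tolerance); DeLong interval
coverage over 500 binormal simulations at n = 50/50 and true AUROC 0.8
(accepted band 0.92–0.975 for the nominal 95% interval, allowing
Monte-Carlo error); oracle equivalences over 50 seeded instances with
n ≤ 200; the end-to-end corpus at δ = 5 with ~45 in-distribution lesions.
Probability vectors must sum to 1 within 1e-9 (1e-6 for black-box
predictor outputs, which are then renormalized); probs/logits consistency
is enforced at 1e-9; rank-preservation assertions use 1e-12.

## Known limitations

* Binary tasks only; no multiclass extension.
* One calibration family (temperature scaling); no Platt/isotonic/focal
  alternatives.
* The single-point rater ROC area is a coarse summary; no multi-reader
  multi-case variance model.
* No adversarial perturbations, vertical flips, zooms, or acquisition
  artifact simulation; the transform battery models mild capture
  variation only.
* RMSE depends on the binning scheme; cross-tool comparisons require the
  same scheme.
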