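# dermastress

Computational **stress tests** for binary image-based diagnostic
classifiers — built for the melanoma-vs-nevus triage setting, usable for
any two-class image classifier that emits per-image class probabilities.

A model that matches expert discrimination on a curated benchmark can
still be unfit for deployment: its confidence may not track its accuracy
(miscalibration), it may assert in-distribution diagnoses on diseases it
never saw (the out-of-distribution problem), and its prediction may flip
when the same lesion is photographed again or the image is mildly rotated
or re-exposed. `dermastress` makes those failure modes measurable, for
any prediction source: a CSV/JSON score table or a black-box
`image -> probability vector` callable.

## What it measures

* **Discrimination** — AUROC with DeLong confidence intervals, AUPR,
  Youden index `J = sens + spec − 1`, F1; operating points matched to a
  human benchmark's sensitivity; model-vs-rater t-tests on J and F1.
* **Calibration** — temperature scaling (`p = softmax(z/T)`, `T` fitted
  by NLL on a validation split) and the ℓ2 / RMS calibration error over
  equal-mass confidence bins,
  `RMSE = sqrt(Σ_b m_b (conf̄_b − acc_b)²)` (0 = perfect, 1 = worst).
* **Selective prediction** — the response-rate accuracy (RRA) curve:
  accuracy among the top-confidence fraction *c* of the test set, its
  area (AURRA), expected-vs-observed accuracy gaps, the gambler's loss
  `−log(p_true + p_reject/o)` for abstention-capable models, and
  per-class rejection rates with exact binomial CIs.
* **OOD auditing** — Wilcoxon rank-sum comparisons of prediction
  confidence on trained-on classes vs classes never seen in training
  (e.g. actinic/seborrheic keratoses for a melanoma/nevus model).
* **Robustness** — replicate-image consistency (all correct / all wrong /
  mixed per lesion), transformation sweeps (rotation, horizontal flip,
  brightness, contrast) with a four-way per-lesion verdict, pooled
  |Δp| statistics, rotation profiles, and test-time augmentation.

Everything runs end-to-end with no external data: a deterministic
synthetic lesion-image generator (class separation controlled by a single
parameter δ, with replicates and OOD families) and a fast, fully
reproducible toy classifier over hand-crafted image features exercise the
whole battery.

## Worked example

```python
import dermastress as ds

# a score table whose miscalibration is exactly temperature 2.5
ps = ds.generate_scored_predictions(n=2000, true_temperature=2.5,
                                    base_auroc=0.85, seed=7)

tm = ds.fit_temperature(ps)
print(tm.temperature)                       # 2.546  (recovers T* = 2.5)

print(ds.rms_calibration_error(ps).rmse)    # 0.1437 (overconfident)
cal = ds.apply_temperature(ps, tm)
print(ds.rms_calibration_error(cal).rmse)   # 0.0399 (after calibration)

roc = ds.roc_with_delong_ci(ps)
print(roc.auroc, roc.auroc_ci)              # 0.8461 (0.8288, 0.8635)

curve = ds.rra_curve(cal, "all")
print(curve.aurra, curve.accuracies[-1])    # 0.9021, 0.785
```

Reading: the scores rank well (AUROC 0.846) but claim far more certainty
than they earn (RMSE 0.14); dividing the logits by the fitted temperature
2.55 repairs that without changing any ranking. The RRA curve shows that
confidence is a useful deferral signal here: committing only on the most
confident cases yields much higher accuracy (AURRA 0.90) than the 78.5%
accuracy at full coverage.

The full battery, on synthetic images with a toy classifier:

```bash
stress battery --synthetic --seed 2 --out-dir out/
```

writes `out/summary.json` plus one CSV per stage (ROC curve, RRA curve,
calibration bins, per-lesion robustness and replicate verdicts, OOD
audit, TTA comparison) and a provenance block. Individual subcommands
(`stress discriminate | calibrate | rra | robustness | replicates | ood |
synth`) wrap single stages; `stress synth --seed 7 --out d/` emits a
byte-reproducible image corpus + manifest.

## Layout

```
src/dermastress/
  data.py            manifests, prediction sets, rater tables, I/O, ensembling
  discrimination.py  ROC/DeLong, AUPR, operating points, rater comparisons
  calibration.py     temperature scaling, RMS calibration error, gap curves
  selective.py       RRA/AURRA, gambler's loss, rejection rates, OOD audit
  robustness.py      transforms, sweeps, replicate consistency, TTA
  synthetic.py       image corpus / score-table / rater generators, toy model
  report.py          battery orchestration, report bundle
  cli.py             the `stress` command
```

See `docs/methods.md` for the statistical conventions (threshold rule,
tie-breaks, binning) and the synthetic generator's assumptions.
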