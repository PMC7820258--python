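"""Image transforms, sweeps, replicate consistency and TTA."""

import numpy as np
import pytest

from dermastress.data import ImageRecord, Manifest
from dermastress.robustness import (
    REPLICATE_CATEGORIES,
    ROBUSTNESS_CATEGORIES,
    TransformSpec,
    apply_transform,
    categorize_sweep,
    default_battery,
    replicate_consistency,
    rotation_profile,
    test_time_augmentation,
    transform_sweep,
)
from tests.conftest import make_pset


def random_image(rng, size):
    return rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)


class TestTransformSpec:
    def test_rotation_normalized_mod_360(self):
        assert TransformSpec("rotation", 360.0).parameter == 0.0
        assert TransformSpec("rotation", 405.0).parameter == 45.0

    def test_ids_round_trip(self):
        for spec in default_battery():
            assert TransformSpec.from_id(spec.transform_id) == spec

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec("brightness", 0.0)
        with pytest.raises(ValueError):
            TransformSpec("contrast", -1.2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec("vertical_flip")


@pytest.mark.parametrize("size", [8, 64, 512])
class TestTransformIdentities:
    def test_rotation_zero_and_full_turn(self, size, rng):
        img = random_image(rng, size)
        assert np.array_equal(apply_transform(img, TransformSpec("rotation", 0.0)), img)
        out = apply_transform(
            img.astype(float) / 255.0, TransformSpec("rotation", 360.0)
        )
        np.testing.assert_allclose(out, img.astype(float) / 255.0, atol=1e-6)

    def test_double_flip_is_identity(self, size, rng):
        img = random_image(rng, size)
        spec = TransformSpec("horizontal_flip")
        assert np.array_equal(apply_transform(apply_transform(img, spec), spec), img)

    def test_neutral_factors(self, size, rng):
        img = random_image(rng, size)
        for spec in (TransformSpec("brightness", 1.0), TransformSpec("contrast", 1.0)):
            assert np.array_equal(apply_transform(img, spec), img)


class TestTransformSemantics:
    def test_rotation_preserves_shape_and_moves_pixels(self, rng):
        img = random_image(rng, 32)
        out = apply_transform(img, TransformSpec("rotation", 90.0))
        assert out.shape == img.shape
        assert not np.array_equal(out, img)

    def test_brightness_scales_and_clips(self):
        img = np.full((4, 4, 3), 200, dtype=np.uint8)
        out = apply_transform(img, TransformSpec("brightness", 1.5))
        assert np.all(out == 255)  # 300 clipped
        out = apply_transform(img, TransformSpec("brightness", 0.5))
        assert np.all(out == 100)

    def test_contrast_fixes_mean_luminance(self, rng):
        img = rng.random((16, 16, 3))
        lum = img @ np.array([0.2125, 0.7154, 0.0721])
        out = apply_transform(img, TransformSpec("contrast", 0.5))
        out_lum = out @ np.array([0.2125, 0.7154, 0.0721])
        assert out_lum.mean() == pytest.approx(lum.mean(), abs=1e-6)
        assert out_lum.std() == pytest.approx(0.5 * lum.std(), rel=1e-3)


def _sweep_manifest(n_lesions=4, truths=("melanoma", "nevus")):
    records = []
    for k in range(n_lesions):
        records.append(
            ImageRecord(f"im{k}", f"L{k}", "d", "test", truths[k % len(truths)])
        )
    return Manifest(records, ("melanoma", "nevus"))


class TestTransformSweep:
    BATTERY = [TransformSpec("rotation", 90.0), TransformSpec("horizontal_flip")]

    def test_invariant_predictor_is_fully_robust(self, rng):
        mf = _sweep_manifest()
        images = {r.image_id: random_image(rng, 16) for r in mf}
        res = transform_sweep(
            lambda img: [0.9, 0.1], mf, self.BATTERY, 0.5, images=images
        )
        cats = {v.category for v in res.verdicts}
        assert cats <= {"consistently_correct", "consistently_wrong"}
        assert res.non_robust_fraction == 0.0
        assert res.median_abs_change == 0.0
        assert all(v.flipping_transforms == () for v in res.verdicts)

    def test_rotation_sensitive_predictor_flagged(self, rng):
        mf = Manifest(
            [ImageRecord("im0", "L0", "d", "test", "melanoma")],
            ("melanoma", "nevus"),
        )
        base = random_image(rng, 16)
        rotated = apply_transform(base, TransformSpec("rotation", 90.0))

        def predictor(img):
            # drops below threshold only on the 90-degree copy
            return [0.2, 0.8] if np.array_equal(img, rotated) else [0.9, 0.1]

        res = transform_sweep(predictor, mf, self.BATTERY, 0.5,
                              images={"im0": base})
        v = res.verdicts[0]
        assert v.category == "correct_original_wrong_transformed"
        assert v.flipping_transforms == ("rotation:90",)

    def test_counts_equal_recount_from_prediction_table(
        self, delta5_corpus, delta5_classifier
    ):
        _, manifest, images = delta5_corpus
        sub = manifest.subset(split="test", include_ood=False)
        res = transform_sweep(
            delta5_classifier, sub, default_battery(), 0.5, images=images,
            positive_class="melanoma",
        )
        # brute-force recount straight from the raw per-record table
        table = {}
        for rec, p in zip(res.predictions.records,
                          res.predictions.positive_scores()):
            m = manifest[rec.image_id]
            table.setdefault(m.lesion_id, []).append(
                (rec.transform_id, (p > 0.5) == (m.true_label == "melanoma"))
            )
        recount = dict.fromkeys(ROBUSTNESS_CATEGORIES, 0)
        for lesion, entries in table.items():
            orig = [ok for tid, ok in entries if tid is None]
            trans = [ok for tid, ok in entries if tid is not None]
            if all(orig) and all(trans):
                recount["consistently_correct"] += 1
            elif not any(orig) and not any(trans):
                recount["consistently_wrong"] += 1
            elif all(orig):
                recount["correct_original_wrong_transformed"] += 1
            else:
                recount["wrong_original_correct_transformed"] += 1
        assert res.category_counts == recount
        assert sum(recount.values()) == len(res.verdicts)

    def test_verdicts_invariant_to_battery_order(self, rng):
        mf = _sweep_manifest()
        images = {r.image_id: random_image(rng, 16) for r in mf}

        def predictor(img):
            p = 0.3 + 0.6 * (img.mean() / 255.0)
            return [p, 1 - p]

        a = transform_sweep(predictor, mf, default_battery(), 0.5, images=images)
        b = transform_sweep(predictor, mf, default_battery()[::-1], 0.5,
                            images=images)
        assert {v.lesion_id: v.category for v in a.verdicts} == {
            v.lesion_id: v.category for v in b.verdicts
        }


class TestRotationProfile:
    def test_invariant_predictor_flat_and_unflagged(self, rng):
        img = random_image(rng, 16)
        prof = rotation_profile(lambda im: [0.8, 0.2], img, 0.5)
        assert set(prof.probabilities) == {0.8}
        assert not prof.crosses_threshold

    def test_trace_above_threshold_not_flagged(self, rng):
        img = random_image(rng, 16)
        prof = rotation_profile(lambda im: [0.6 + 0.01 * im[0, 0, 0] / 255, 0],
                                img, 0.5, degrees_grid=[0, 90])
        assert not prof.crosses_threshold

    def test_sinusoidal_response_crossings_match_construction(self):
        # predictor responds to the rotation angle itself via a marker pixel
        size = 8

        def make_image(angle):
            img = np.zeros((size, size, 3))
            img[0, 0, 0] = angle / 360.0
            return img

        def predictor(img):
            angle = float(img[0, 0, 0]) * 360.0
            p = 0.5 + 0.3 * np.sin(np.deg2rad(angle))
            return [p, 1 - p]

        grid = list(range(0, 360, 15))
        probs = [predictor(make_image(a))[0] for a in grid]
        above = [p > 0.5 for p in probs]
        assert any(above) and not all(above)  # crosses by construction


class TestReplicateConsistency:
    def _pset(self, lesion_probs, truth):
        scores, labels, lesions, ids = [], [], [], []
        for li, (lesion, probs) in enumerate(lesion_probs.items()):
            for j, p in enumerate(probs):
                scores.append(p)
                labels.append(truth[lesion])
                lesions.append(lesion)
                ids.append(f"{lesion}_i{j}")
        return make_pset(scores, labels, image_ids=ids, lesion_ids=lesions)

    def test_both_above_threshold_all_correct(self):
        ps = self._pset({"L1": [0.6, 0.7]}, {"L1": "melanoma"})
        res = replicate_consistency(ps, 0.209)
        assert res.verdicts[0].category == "all_correct"

    def test_straddling_threshold_is_mixed(self):
        ps = self._pset({"L1": [0.25, 0.15]}, {"L1": "melanoma"})
        res = replicate_consistency(ps, 0.209)
        assert res.verdicts[0].category == "mixed"

    def test_single_image_lesions_counted_not_judged(self):
        ps = self._pset({"L1": [0.6], "L2": [0.3]},
                        {"L1": "melanoma", "L2": "nevus"})
        res = replicate_consistency(ps, 0.5)
        assert res.verdicts == []
        assert res.n_single_image_lesions == 2

    def test_categories_partition_multi_image_lesions(self, rng):
        lesion_probs = {
            f"L{k}": list(rng.random(int(rng.integers(2, 4)))) for k in range(12)
        }
        truth = {k: ("melanoma" if rng.random() < 0.4 else "nevus")
                 for k in lesion_probs}
        ps = self._pset(lesion_probs, truth)
        res = replicate_consistency(ps, 0.31)
        assert sum(res.category_counts.values()) == len(res.verdicts) == 12
        assert set(res.category_counts) == set(REPLICATE_CATEGORIES)
        assert sum(res.category_percentages.values()) == pytest.approx(100.0)


class TestTTA:
    def test_invariant_predictor_unchanged(self, rng):
        img = random_image(rng, 16)
        out = test_time_augmentation(lambda im: [0.7, 0.3], img,
                                     default_battery())
        np.testing.assert_allclose(out, [0.7, 0.3], atol=1e-12)

    def test_two_copy_mean(self, rng):
        img = random_image(rng, 16)
        flipped = apply_transform(img, TransformSpec("horizontal_flip"))

        def predictor(im):
            return [0.8, 0.2] if np.array_equal(im, flipped) else [0.2, 0.8]

        out = test_time_augmentation(
            predictor, img, [TransformSpec("horizontal_flip")]
        )
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_paired_auroc_evaluation_runs(self, delta5_corpus, delta5_classifier):
        from sklearn.metrics import roc_auc_score

        _, manifest, images = delta5_corpus
        sub = manifest.subset(split="test", include_ood=False)
        y, p0, pt = [], [], []
        for rec in sub:
            y.append(int(rec.true_label == "melanoma"))
            p0.append(delta5_classifier(images[rec.image_id])[0])
            pt.append(
                test_time_augmentation(
                    delta5_classifier, images[rec.image_id],
                    default_battery()[:4],
                )[0]
            )
        a0 = roc_auc_score(y, p0)
        at = roc_auc_score(y, pt)
        # no direction asserted; both must be valid AUROCs on the same labels
        assert 0.0 <= a0 <= 1.0 and 0.0 <= at <= 1.0
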