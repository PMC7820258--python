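import numpy as np
import pytest

from dermastress.data import (
    ImageRecord,
    Manifest,
    PredictionRecord,
    PredictionSet,
)
from dermastress.synthetic import SyntheticConfig, generate_image_corpus, toy_classifier
from dermastress.data import apply_predictor

CLASSES = ("melanoma", "nevus")


def make_pset(
    pos_scores,
    labels,
    *,
    image_ids=None,
    lesion_ids=None,
    split="test",
    logits=None,
    positive_class="melanoma",
    class_names=CLASSES,
):
    """Build a binary PredictionSet from positive-class probabilities.

    ``labels`` may contain class names outside ``class_names``; those
    records are flagged OOD automatically.
    """
    n = len(pos_scores)
    if image_ids is None:
        image_ids = [f"img{i:04d}" for i in range(n)]
    if lesion_ids is None:
        lesion_ids = image_ids
    manifest = Manifest(
        [
            ImageRecord(image_ids[i], lesion_ids[i], "fixture", split, labels[i])
            for i in range(n)
        ],
        class_names,
    )
    records = []
    for i, p in enumerate(pos_scores):
        z = None if logits is None else tuple(logits[i])
        records.append(
            PredictionRecord(image_ids[i], (float(p), float(1 - p)), logits=z)
        )
    return PredictionSet(records, manifest, positive_class)


@pytest.fixture(scope="session")
def delta5_corpus():
    """Well-separated synthetic corpus with OOD classes (shared, read-only)."""
    cfg = SyntheticConfig(
        seed=3,
        delta=5.0,
        ood_lesions={"actinic_keratosis": 6, "seborrheic_keratosis": 6},
    )
    manifest, images = generate_image_corpus(cfg)
    return cfg, manifest, images


@pytest.fixture(scope="session")
def delta5_classifier(delta5_corpus):
    _, manifest, images = delta5_corpus
    return toy_classifier(manifest, images)


@pytest.fixture(scope="session")
def delta5_test_set(delta5_corpus, delta5_classifier):
    """Toy-classifier predictions on the in-distribution test split."""
    _, manifest, images = delta5_corpus
    sub = manifest.subset(split="test", include_ood=False)
    return apply_predictor(
        delta5_classifier, sub, images=images, positive_class="melanoma"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
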