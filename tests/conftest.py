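import numpy as np
import pytest

from uncertram.data_model import Annotation, AnnotationSet


def make_set(scores, reviewers=None, image_id="img"):
    """AnnotationSet from a score list (reviewers default to 1..k)."""
    if reviewers is None:
        reviewers = range(1, len(scores) + 1)
    return AnnotationSet(image_id, [Annotation(r, s)
                                    for r, s in zip(reviewers, scores)])


@pytest.fixture
def example_set():
    """The worked three-reviewer example: scores 6, 2, 2 by reviewers 8, 6, 12."""
    return make_set([6, 2, 2], reviewers=[8, 6, 12])


@pytest.fixture
def tiny_dataset():
    """A small annotated synthetic dataset shared by protocol tests."""
    from uncertram.synthetic import SynthConfig, generate_dataset
    from uncertram.training import annotate_labels

    config = SynthConfig(n_patients=12, images_per_patient=(2, 3),
                         image_size=16, seed=42)
    dataset, latent = generate_dataset(config)
    return annotate_labels(dataset), latent


@pytest.fixture
def rng():
    return np.random.default_rng(0)
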