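"""Shared fixtures: one default phantom, classified once per session.

The default phantom (64 x 96 x 96 voxels at 10 um, 8 mirrored regions,
25 cells per region) is the study condition most tests run against; the
expensive steps — feature extraction, forest training, prediction — are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from stptquant import classify, phantom
from stptquant.phantom import GroundTruth, PhantomSpec
from stptquant.register import AtlasBundle
from stptquant.volio import VolumeStack


@pytest.fixture(scope="session")
def base_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def toy_atlas(base_spec) -> AtlasBundle:
    return phantom.generate_atlas(base_spec)


@pytest.fixture(scope="session")
def phantom_data(base_spec, toy_atlas) -> tuple[VolumeStack, GroundTruth]:
    return phantom.generate_stack(base_spec, toy_atlas)


@pytest.fixture(scope="session")
def annotations(phantom_data):
    stack, truth = phantom_data
    return phantom.generate_annotations(truth, stack, seed=2)


@pytest.fixture(scope="session")
def stack_features(phantom_data):
    stack, _ = phantom_data
    return classify.compute_features_stack(stack)


@pytest.fixture(scope="session")
def classifier(stack_features, annotations):
    return classify.train_classifier(stack_features, annotations, seed=3)


@pytest.fixture(scope="session")
def label_probabilities(classifier, stack_features) -> dict[str, np.ndarray]:
    return classify.predict_probabilities(classifier, stack_features)


@pytest.fixture(scope="session")
def cell_probmap(label_probabilities, base_spec):
    return classify.export_probability_map(
        label_probabilities["cell_bodies"],
        "cell_bodies",
        base_spec.voxel_size_um,
        base_spec.voxel_size_um,
    )
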