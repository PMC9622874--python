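import numpy as np
import pytest

from crosstalk.core_io import LabeledDrugSet, PipelineConfig
from crosstalk.synthetic import (
    DescriptorBlock,
    SyntheticSpec,
    simulate_descriptors,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def labeled_descriptors():
    """Default-scale planted descriptor matrix (16/24, 6 informative, delta=3)."""
    spec = SyntheticSpec(seed=11)
    matrix, labels, planted = simulate_descriptors(spec)
    drug_set = LabeledDrugSet(
        positives=frozenset(d for d, c in labels.items() if c == "positive"),
        negatives=frozenset(d for d, c in labels.items() if c == "negative"),
    )
    return matrix, drug_set, planted


@pytest.fixture
def separable_descriptors():
    """Two far-apart clusters: informative columns only, delta = 10 pooled SDs."""
    spec = SyntheticSpec(seed=23)
    spec.descriptors = DescriptorBlock(
        n_pos=16, n_neg=24, n_informative=6, separation=10.0,
        n_constant=0, n_correlated_pairs=0, n_low_entropy=0, n_noise=0,
    )
    matrix, labels, planted = simulate_descriptors(spec)
    matrix = matrix.subset_features(planted["informative"])
    drug_set = LabeledDrugSet(
        positives=frozenset(d for d, c in labels.items() if c == "positive"),
        negatives=frozenset(d for d, c in labels.items() if c == "negative"),
    )
    return matrix, drug_set
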