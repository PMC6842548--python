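import numpy as np
import pytest

from purank import FeatureMatrix, LabelState, RunConfig, SyntheticSpec, generate


@pytest.fixture
def tiny_matrix() -> FeatureMatrix:
    """5 genes x 3 features with two source blocks."""
    values = np.array([
        [1, 1, 0],
        [1, 1, 0],
        [1, 1, 0],
        [0, 0, 1],
        [0, 0, 1],
    ])
    return FeatureMatrix(
        gene_ids=["g1", "g2", "g3", "g4", "g5"],
        feature_ids=["f1", "f2", "f3"],
        values=values,
        source_blocks={"a": ["f1", "f2"], "b": ["f3"]},
    )


@pytest.fixture
def tiny_labels(tiny_matrix) -> LabelState:
    return LabelState(positives={"g1", "g2"}, unlabeled={"g3", "g4", "g5"})


@pytest.fixture(scope="session")
def default_instance():
    """One default-spec synthetic PU instance, shared across tests."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def separated_instance():
    """Strongly separated instance (p1=0.9 / p0=0.1)."""
    return generate(SyntheticSpec(p1=0.9, p0=0.1, seed=7))


@pytest.fixture
def fast_config() -> RunConfig:
    """Small but spec-shaped config for quick pipeline runs."""
    return RunConfig(random_seed=7)
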