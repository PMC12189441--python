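import numpy as np
import pytest

from ssokd.synthetic import SyntheticSpec, generate_dataset
from ssokd.pipeline import stratified_split
from ssokd.workflow import WorkflowConfig, prepare_arrays


@pytest.fixture(scope="session")
def small_dataset():
    spec = SyntheticSpec(n_samples=160, seed=7)
    return spec, generate_dataset(spec)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    _, samples = small_dataset
    return stratified_split(samples, seed=7)


@pytest.fixture(scope="session")
def small_arrays(small_split):
    cfg = WorkflowConfig(seed=7, augment=False)
    return prepare_arrays(small_split, cfg)


@pytest.fixture(scope="session")
def micro_arrays():
    """A very small 16x16 dataset for fast training tests."""
    spec = SyntheticSpec(n_samples=80, image_size=16, seed=11)
    samples = generate_dataset(spec)
    split = stratified_split(samples, seed=11)
    from ssokd.preprocessing import PreprocessConfig
    cfg = WorkflowConfig(
        seed=11, augment=False,
        preprocess=PreprocessConfig(target_shape=(16, 16, 1)))
    return prepare_arrays(split, cfg)
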