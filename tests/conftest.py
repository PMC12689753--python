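import numpy as np
import pytest

from qdcnn.phantom import DatasetConfig, build_dataset
from qdcnn.sigmodel import EchoSchedule, default_schedule


@pytest.fixture(scope="session")
def schedule16() -> EchoSchedule:
    return default_schedule()


@pytest.fixture(scope="session")
def schedule4() -> EchoSchedule:
    return EchoSchedule(tes=np.array([10.0, 60.0, 110.0, 160.0]), tr=7000.0)


@pytest.fixture(scope="session")
def tiny_cfg() -> DatasetConfig:
    """Very small dataset for fast structural tests."""
    return DatasetConfig(
        n_cases=3,
        n_train=1,
        n_val=1,
        n_test=1,
        n_slices=2,
        h=32,
        w=32,
        af=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    cases, manifest = build_dataset(tiny_cfg)
    return cases, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
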