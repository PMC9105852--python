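import numpy as np
import pytest

from roitone.synthdata import LabeledDataset, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset() -> LabeledDataset:
    """The full default synthetic dataset (200 normal / 300 cirrhosis)."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """A reduced dataset (60/90) for cheap pipeline tests."""
    return generate_dataset(SyntheticConfig(n_normal=60, n_cirrhosis=90, seed=5))


def make_stub_dataset(n_normal: int, n_cirrhosis: int, size: int = 8, seed: int = 0):
    """Random-noise dataset with no class signal, for harness-level tests."""
    rng = np.random.default_rng(seed)
    n = n_normal + n_cirrhosis
    images = rng.integers(0, 256, size=(n, size, size))
    labels = np.array([0] * n_normal + [1] * n_cirrhosis, np.int8)
    ids = tuple(f"img_{i:04d}" for i in range(n))
    return LabeledDataset(images, labels, ids, 255)
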