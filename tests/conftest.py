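import numpy as np
import pytest

from metaselect import MetaDataset


@pytest.fixture
def toy3() -> MetaDataset:
    """Three-study meta-analysis with hand-checkable weighted means."""
    return MetaDataset([0.1, 0.2, 0.3], [0.3, 0.4, 0.5])


@pytest.fixture
def boundary5() -> MetaDataset:
    """Five studies whose RE fit lands on the tau2 = 0 boundary."""
    return MetaDataset([0.12, 0.35, -0.10, 0.42, 0.08], [0.20, 0.30, 0.40, 0.50, 0.60])


@pytest.fixture
def dispersed5() -> MetaDataset:
    """Five dispersed studies with an interior tau2 ML solution."""
    return MetaDataset([0.80, -0.30, 0.55, 1.20, 0.05], [0.20, 0.30, 0.40, 0.50, 0.60])


def random_dataset(rng: np.random.Generator, n: int | None = None) -> MetaDataset:
    """A random but well-conditioned meta-analysis for property tests."""
    if n is None:
        n = int(rng.integers(2, 13))
    y = rng.normal(0.0, 1.0, size=n)
    s = rng.uniform(0.05, 1.5, size=n)
    return MetaDataset(y, s)
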