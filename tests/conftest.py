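import numpy as np
import pytest

from lrrmeta import ArmSummary, MetaDataset


@pytest.fixture
def toy_equal_var() -> MetaDataset:
    """Three studies with effects (0, 0.5, 1.0) and equal variance 0.1;
    every moment-based tau2 estimator has the closed form max(0, S^2 - v^2)
    here, which equals 0.15."""
    return MetaDataset.from_arrays([0.0, 0.5, 1.0], [0.1, 0.1, 0.1])


@pytest.fixture
def homogeneous() -> MetaDataset:
    return MetaDataset.from_arrays([0.3, 0.3, 0.3, 0.3], [0.05, 0.1, 0.2, 0.08])


def random_dataset(rng: np.random.Generator, k: int | None = None) -> MetaDataset:
    """A random small meta-analysis with moderate heterogeneity."""
    k = k or int(rng.integers(3, 12))
    y = rng.normal(0.2, 0.5, size=k)
    v = rng.uniform(0.01, 0.2, size=k)
    return MetaDataset.from_arrays(y, v)


def random_arm_dataset(rng: np.random.Generator, k: int = 6) -> MetaDataset:
    """Random dataset with arm-level summaries (needed by SSW)."""
    arms = []
    for _ in range(k):
        n_t, n_c = rng.integers(10, 120, size=2)
        m_c = rng.uniform(2.0, 6.0)
        m_t = m_c * np.exp(rng.normal(0.1, 0.3))
        arms.append(
            (
                ArmSummary(int(n_t), m_t, m_t * rng.uniform(0.2, 0.5)),
                ArmSummary(int(n_c), m_c, m_c * rng.uniform(0.2, 0.5)),
            )
        )
    return MetaDataset.from_arms(arms)
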