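import numpy as np
import pytest

from iggaucs.data import SurvivalDataset
from iggaucs.groups import GroupStructure, contiguous_groups


def random_dataset(
    n: int = 30,
    m: int = 4,
    censor_frac: float = 0.3,
    seed: int = 0,
    tie_times: bool = False,
) -> SurvivalDataset:
    """Small random survival dataset with controllable censoring and ties."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    t = rng.exponential(1.0, size=n)
    if tie_times:
        t = np.round(t, 1)
    delta = (rng.uniform(size=n) > censor_frac).astype(int)
    if delta.sum() == 0:
        delta[0] = 1
    return SurvivalDataset(X=X, t=t, delta=delta)


@pytest.fixture
def small_ds() -> SurvivalDataset:
    return random_dataset(n=30, m=4, seed=1)


@pytest.fixture
def all_events_ds() -> SurvivalDataset:
    return random_dataset(n=25, m=3, censor_frac=0.0, seed=2)


@pytest.fixture
def two_group_structure() -> GroupStructure:
    return contiguous_groups(4, 2)


@pytest.fixture
def dataset_factory():
    return random_dataset
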