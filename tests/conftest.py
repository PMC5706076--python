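import numpy as np
import pytest

from stabselcox import SurvivalDataset


@pytest.fixture
def two_event_dataset() -> SurvivalDataset:
    """Smallest useful case: two subjects, both failing, one covariate."""
    return SurvivalDataset(
        X=np.array([[1.0], [-1.0]]), times=[1.0, 2.0], events=[1, 1]
    )


def random_dataset(
    rng: np.random.Generator,
    n: int = 40,
    p: int = 5,
    censor_frac: float = 0.3,
    beta_scale: float = 1.0,
) -> SurvivalDataset:
    """Small random survival dataset for property checks."""
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * beta_scale
    times = -np.log(rng.uniform(size=n)) * np.exp(-np.clip(X @ beta, -30, 30))
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[np.argmin(times)] = 1
    return SurvivalDataset(X=X, times=times, events=events)
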