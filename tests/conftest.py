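import numpy as np
import pytest

from affectvar import (
    FilterConfig,
    RatingSeries,
    demo_regime_schedule,
    simulate_regimes,
)


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig.default((0.0, 1.0))


@pytest.fixture(scope="session")
def regime_series():
    """One 360-day series from the benchmark regime schedule."""
    _, series = simulate_regimes(demo_regime_schedule(), 0.5, seed=1)
    return series


@pytest.fixture
def short_series():
    rng = np.random.default_rng(42)
    vals = np.clip(rng.normal(0.5, 0.1, size=20), 0, 1)
    return RatingSeries("p1", "positive", np.arange(1, 21), vals, (0.0, 1.0))


def make_series(values, days=None, bounds=(0.0, 1.0), valence="positive"):
    values = np.asarray(values, dtype=float)
    if days is None:
        days = np.arange(1, len(values) + 1)
    return RatingSeries("t", valence, np.asarray(days), values, bounds)
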