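import numpy as np
import pandas as pd
import pytest

import expotox as ex


@pytest.fixture(scope="session")
def env_series():
    """Two years of daily multichannel environmental data."""
    return ex.generate_env(ex.EnvGenConfig(n_days=730, seed=11))


@pytest.fixture(scope="session")
def health_panel(env_series):
    """5000-record health panel with one negative, one null and one
    positive planted exposure association."""
    cfg = ex.HealthGenConfig(
        n_records=5000, n_features=24, seed=12,
        indicators=(
            ex.IndicatorSpec("neg", -0.6, 0.25),
            ex.IndicatorSpec("null", 0.0, 0.15),
            ex.IndicatorSpec("pos", 0.45, 0.3),
        ),
    )
    return ex.generate_health(cfg, env_series)


@pytest.fixture
def small_labels():
    mat = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 0],
                    [1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 0, 1]])
    return ex.MultiLabelSet(names=["a", "b", "c"], matrix=mat)
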