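import numpy as np
import pandas as pd
import pytest

from actisleep import SimulationConfig
from actisleep.simulate import EpochSeries, simulate_epoch_cohort


def make_series(
    activity: np.ndarray,
    epoch_len: int = 60,
    start: str = "2023-03-06 12:00",
    light: np.ndarray | None = None,
    wear: np.ndarray | None = None,
    pid: str = "T000",
) -> EpochSeries:
    """Hand-built epoch series for rule-boundary tests."""
    n = len(activity)
    ts = pd.date_range(start, periods=n, freq=f"{epoch_len}s")
    return EpochSeries(
        pid,
        pd.DataFrame(
            {
                "timestamp": ts,
                "activity": np.asarray(activity, dtype=float),
                "light": np.zeros(n) if light is None else np.asarray(light, dtype=float),
                "wear": np.ones(n, dtype=bool) if wear is None else np.asarray(wear, dtype=bool),
            }
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 8-participant, 7-day epoch cohort with ground truth."""
    cfg = SimulationConfig(n_participants=8, n_days=7, seed=42, nonwear_rate=1.0)
    series, truth = simulate_epoch_cohort(cfg)
    return cfg, series, truth
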