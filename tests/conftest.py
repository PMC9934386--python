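import numpy as np
import pandas as pd
import pytest

from gulltrack.synthetic import SyntheticConfig, generate_cohort
from gulltrack.track_store import Track


def make_track(bird_id, times, lats, lons, alts=None, volts=None) -> Track:
    """Build a Track from plain lists; times parseable, assumed UTC."""
    ts = pd.to_datetime(list(times), utc=True)
    n = len(ts)
    return Track(
        bird_id=bird_id,
        fixes=pd.DataFrame(
            {
                "bird_id": bird_id,
                "timestamp": ts,
                "lat": np.asarray(lats, float),
                "lon": np.asarray(lons, float),
                "altitude_m": np.asarray(alts, float) if alts is not None else np.full(n, np.nan),
                "voltage_v": np.asarray(volts, float) if volts is not None else np.full(n, np.nan),
            }
        ),
    )


@pytest.fixture(scope="session")
def quiet_cohort():
    """10 breeders, 1 year, 2 h duty, every noise source off: exact ground truth."""
    cfg = SyntheticConfig(n_birds=10, years=1, seed=7).quiet()
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default (noisy, artifact-injecting) cohort with two non-breeders."""
    cfg = SyntheticConfig(n_birds=8, years=1, n_nonbreeders=2, seed=12)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_year_cohort():
    """Multi-year cohort for repeatability analyses."""
    cfg = SyntheticConfig(n_birds=5, years=2, seed=21)
    return cfg, generate_cohort(cfg)
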