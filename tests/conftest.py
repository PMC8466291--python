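import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A full synthetic study on disk (299 calves, printed exclusions)."""
    from calftherm.simulate import generate_study

    outdir = tmp_path_factory.mktemp("study")
    generate_study(outdir, seed=42)
    return outdir


@pytest.fixture()
def flat_climate():
    """Constant-climate helper: a frame of identical hourly records."""

    def _make(n_hours, air_temp=10.0, rh=80.0, wind=0.0,
              start="2019-01-01"):
        ts = pd.date_range(start, periods=n_hours, freq="h")
        return pd.DataFrame({
            "timestamp": ts,
            "air_temp": np.full(n_hours, float(air_temp)),
            "rel_humidity": np.full(n_hours, float(rh)),
            "wind_speed": np.full(n_hours, float(wind)),
        })

    return _make
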