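import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenoswap.plate_io import CalibrationModel, CorrectedSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_corrected(times, log_od, well_id="T1", **meta) -> CorrectedSeries:
    """Build a CorrectedSeries directly from a log-OD array (test helper)."""
    log_od = np.asarray(log_od, dtype=float)
    od = np.where(np.isfinite(log_od), np.exp(log_od), 1e-6)
    return CorrectedSeries(
        well_id=well_id,
        times=np.asarray(times, dtype=float),
        od_raw=od,
        od_corr=od,
        log_od=log_od,
        **meta,
    )


@pytest.fixture
def identity_model() -> CalibrationModel:
    return CalibrationModel()


@pytest.fixture
def grid_24h() -> np.ndarray:
    """24 h at the 10-min cadence."""
    return np.arange(0.0, 24.0 + 1e-9, 1.0 / 6.0)
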