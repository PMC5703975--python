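import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from karstmix import WATER_MASS_STATS

settings.register_profile(
    "fast",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture
def table1_means() -> pd.DataFrame:
    """One row per subterranean water mass at its published mean values."""
    rows = []
    for wm, stats in WATER_MASS_STATS.items():
        row = {"sample_id": f"{wm}-mean", "event": "pooled", "water_mass": wm}
        for var, (mean, _se, _n) in stats.items():
            row[var] = mean
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def table1_means_csv(tmp_path, table1_means):
    path = tmp_path / "table1_means.csv"
    table1_means.to_csv(path, index=False)
    return path
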