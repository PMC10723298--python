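import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def clone_csv(tmp_path):
    """Write a records frame to CSV and return its path."""

    def _write(df: pd.DataFrame, name: str = "clones.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def small_table_df():
    """Six clones at two passages with known survival fractions."""
    rows = []
    fractions = {1: [0.8, 1.0, 1.2, 0.9, 0.7, 1.1], 3: [0.9, 0.8, 1.0, 1.1, 0.95, 0.85]}
    for passage, fr in fractions.items():
        for i, f in enumerate(fr):
            rows.append(
                {
                    "clone_id": f"c{i}",
                    "passage": passage,
                    "plated_count": 1000,
                    "live_count": int(round(f * 1000)),
                }
            )
    return pd.DataFrame(rows)
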