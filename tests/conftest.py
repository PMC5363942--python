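import numpy as np
import pandas as pd
import pytest

from racvd import simulate as sim
from racvd.schema import empty_frame


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """A schema-complete frame from partial row dicts (rest missing)."""
    cols = list(empty_frame(0).columns)
    defaults = {"age": 55.0, "sex": "female", "followup_time": 5.0, "cvd_event": 0}
    filled = [
        {**{c: np.nan for c in cols}, **defaults,
         "id": f"T{i:03d}", "cohort_id": "toy", **r}
        for i, r in enumerate(rows)
    ]
    return pd.DataFrame(filled, columns=cols)


@pytest.fixture(scope="session")
def toy_km_frame():
    """Six subjects with hand-computable product-limit estimates:
    events at t = 1, 3, 5, 6; censorings at 2 and 4."""
    rows = [
        {"followup_time": 1.0, "cvd_event": 1},
        {"followup_time": 2.0, "cvd_event": 0},
        {"followup_time": 3.0, "cvd_event": 1},
        {"followup_time": 4.0, "cvd_event": 0},
        {"followup_time": 5.0, "cvd_event": 1},
        {"followup_time": 6.0, "cvd_event": 1},
    ]
    return make_frame(rows)


@pytest.fixture(scope="session")
def small_ds():
    """Complete (no missingness) two-stratum dataset, ~1600 subjects."""
    cfg = sim.two_strata_config(n_per_stratum=800, seed=7)
    return sim.generate_multicohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_df(small_ds):
    df = small_ds.data.copy()
    df["stratum"] = small_ds.stratum_of().to_numpy()
    return df


@pytest.fixture(scope="session")
def study_ds_small():
    """Scaled-down 13-cohort dataset with the default missingness plan."""
    cfg = sim.default_config(missingness=True, seed=3, n_scale=0.3)
    return sim.generate_multicohort(cfg, seed=3)
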