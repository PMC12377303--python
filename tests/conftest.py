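import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from exhazard import LifeTable, make_toy_lifetable

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def toy_table():
    """Default Gompertz-like toy life table, 1988-2019."""
    return make_toy_lifetable()


@pytest.fixture(scope="session")
def flat_table():
    """Single-stratum table with one band 0-120 and q = 1 - exp(-0.02)."""
    q = -np.expm1(-0.02)
    cells = pd.DataFrame(
        [
            ("female", "White", y, 0, 120, q)
            for y in range(2000, 2003)
        ]
        + [
            ("male", "White", y, 0, 120, q)
            for y in range(2000, 2003)
        ],
        columns=["sex", "race", "year", "age_lo", "age_hi", "annual_q"],
    )
    return LifeTable(cells)


def make_intervals(durations, deaths, expected, sex=None, band="[0,inf)"):
    """Hand-built person-time table for direct likelihood tests."""
    n = len(durations)
    t = np.asarray(durations, dtype=float)
    start = np.zeros(n)
    df = pd.DataFrame(
        {
            "candidate_id": [f"x{i}" for i in range(n)],
            "t_start": start,
            "t_stop": t,
            "duration": t,
            "death": np.asarray(deaths, dtype=int),
            "expected_hazard": np.asarray(expected, dtype=float),
            "followup_band": band,
            "age_category": "25-44",
            "calendar_year": 2000,
            "age_years": 30.0,
            "sex": sex if sex is not None else ["male"] * n,
            "race": "White",
            "primary_disease": "other",
            "organ": "kidney",
            "listing_year": 2000,
        }
    )
    df["era"] = "1999-2008"
    return df


@pytest.fixture
def intervals_factory():
    return make_intervals
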