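import numpy as np
import pandas as pd
import pytest

from cwsfluoride import spatial
from cwsfluoride.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate(SyntheticConfig(seed=42))


@pytest.fixture()
def line_weights():
    """Row-standardized path graph 1-2-3-4."""
    return spatial.build_queen_weights([(0, 1), (1, 2), (2, 3)], [0, 1, 2, 3])


@pytest.fixture()
def grid22_weights():
    """2x2 queen grid: complete graph on four counties."""
    from cwsfluoride.synthetic import generate_grid_adjacency

    edges = generate_grid_adjacency(2, 2)
    ids = sorted({i for e in edges for i in e})
    return spatial.build_queen_weights(edges, ids)


def make_records(rows):
    """Build a monitoring-record frame from (sys, date, value, units, lod, detected, type)."""
    return pd.DataFrame(
        rows,
        columns=["system_id", "sample_date", "value", "units", "lod", "detected", "sample_type"],
    )


@pytest.fixture()
def hand_fixture():
    """Ten hand-built records exercising nondetects, mg/L and the raw override.

    Expected values (exact, sqrt2 = 2**0.5):
      S1 2006: treated {500, 700}, raw {1200} -> treated-only mean 600
      S1 2007: nondetect lod 0.2 mg/L -> 200/sqrt2; treated 300 -> (300 + 200/sqrt2)/2
      S1 2009: treated 450 -> 450
      S1 mean = (1200 + 50*sqrt2)/3
      S2 2006: raw-only 800 -> 800
      S2 2008: treated 400, raw 300 -> all-sample mean 350
      S2 2010: nondetect lod 100 -> 100/sqrt2
      S2 mean = (1150 + 50*sqrt2)/3
      county X (pops 9000/1000): weighted mean (1195 + 50*sqrt2)/3, P90 = P95 = S1 mean
    """
    records = make_records(
        [
            ("S1", "2006-03-01", 0.5, "mg/L", 0.1, True, "treated"),
            ("S1", "2006-06-01", 700.0, "ug/L", 100.0, True, "treated"),
            ("S1", "2006-09-01", 1.2, "mg/L", 0.1, True, "raw"),
            ("S1", "2007-02-01", np.nan, "mg/L", 0.2, False, "treated"),
            ("S1", "2007-08-01", 300.0, "ug/L", 100.0, True, "treated"),
            ("S1", "2009-05-01", 0.45, "mg/L", 0.1, True, "treated"),
            ("S2", "2006-04-01", 800.0, "ug/L", 100.0, True, "raw"),
            ("S2", "2008-07-01", 400.0, "ug/L", 100.0, True, "treated"),
            ("S2", "2008-10-01", 300.0, "ug/L", 100.0, True, "raw"),
            ("S2", "2010-01-01", np.nan, "ug/L", 100.0, False, "treated"),
        ]
    )
    inventory = pd.DataFrame(
        {
            "system_id": ["S1", "S2"],
            "county_id": ["X", "X"],
            "population_served": [9000, 1000],
            "source_type": ["groundwater", "groundwater"],
            "region": ["Southwest", "Southwest"],
            "cluster": ["Rural, High SES", "Rural, High SES"],
            "tribal": [False, False],
            "correctional": [False, False],
            "fluoridation_reported": [np.nan, 1.0],
            "size_category": ["3301-10000", "501-3300"],
        }
    )
    counties = pd.DataFrame({"county_id": ["X"], "public_water_population": [10_000]})
    sqrt2 = 2.0 ** 0.5
    expected = {
        "S1": (1200.0 + 50.0 * sqrt2) / 3.0,
        "S2": (1150.0 + 50.0 * sqrt2) / 3.0,
        "county_mean": (1195.0 + 50.0 * sqrt2) / 3.0,
    }
    return records, inventory, counties, expected
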