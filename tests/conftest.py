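import numpy as np
import pandas as pd
import pytest

from ohcasim import AmputationSpec, Table1Counts, ampute, generate_model_based, generate_table_faithful


@pytest.fixture(scope="session")
def table1() -> Table1Counts:
    return Table1Counts.default()


@pytest.fixture(scope="session")
def full_cohort(table1) -> pd.DataFrame:
    """Scale-1 table-faithful cohort (13,274 rows)."""
    return generate_table_faithful(table1, scale=1.0, seed=20240901)


@pytest.fixture(scope="session")
def small_cohort(table1) -> pd.DataFrame:
    """A ~2000-row table-faithful cohort for fast tests (large enough to
    populate the small unknown-rhythm cell on both outcome arms)."""
    return generate_table_faithful(table1, scale=0.15, seed=3)


@pytest.fixture(scope="session")
def model_cohort():
    """Model-based cohort with known truth (n=4000)."""
    table, true = generate_model_based(4000, seed=11)
    return table, true


@pytest.fixture(scope="session")
def amputed_small(small_cohort):
    """The small cohort after 20% MAR amputation, plus its mask."""
    table, mask = ampute(small_cohort, AmputationSpec(0.20), seed=5)
    return table, mask


def toy_table(rows: dict) -> pd.DataFrame:
    """Build a cohort-like frame from per-column lists, defaulting the rest."""
    n = max(len(v) for v in rows.values())
    base = {
        "case_id": list(range(1, n + 1)),
        "age": [50.0] * n,
        "gender": ["female"] * n,
        "witness_type": ["not_witnessed"] * n,
        "arrest_location": ["home"] * n,
        "call_time": ["t00_05"] * n,
        "first_rhythm": ["non_shockable"] * n,
        "alert_issued": [0] * n,
        "bcpr": [0] * n,
    }
    base.update(rows)
    df = pd.DataFrame(base)
    df["age"] = df["age"].astype(float)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
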