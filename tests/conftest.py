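import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixture_records():
    """5 countries x 10 years x 6 crops, deterministic areas: 300 records."""
    rows = []
    for ci in range(5):
        for year in range(2000, 2010):
            for ki in range(6):
                rows.append(
                    {
                        "country": f"C{ci + 1}",
                        "year": year,
                        "crop_group": f"crop{ki + 1}",
                        "area_ha": float(10 + ci + ki + (year - 2000) * 0.5),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def faostat_csv(tmp_path, fixture_records):
    """The fixture records written in the FAOSTAT bulk-download dialect."""
    out = pd.DataFrame(
        {
            "Area": fixture_records["country"],
            "Item": fixture_records["crop_group"],
            "Element": "Area harvested",
            "Year": fixture_records["year"],
            "Unit": "ha",
            "Value": fixture_records["area_ha"],
        }
    )
    path = tmp_path / "production.csv"
    out.to_csv(path, index=False)
    return path


def piecewise_series(years, s0, psi1, psi2, slopes):
    """Independent piecewise mean used by test oracles (hand-written form)."""
    years = np.asarray(years, dtype=float)
    out = np.empty_like(years)
    for i, t in enumerate(years):
        if t <= psi1:
            out[i] = s0 + slopes[0] * (t - years[0])
        elif t <= psi2:
            out[i] = (
                s0 + slopes[0] * (psi1 - years[0]) + slopes[1] * (t - psi1)
            )
        else:
            out[i] = (
                s0
                + slopes[0] * (psi1 - years[0])
                + slopes[1] * (psi2 - psi1)
                + slopes[2] * (t - psi2)
            )
    return out
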