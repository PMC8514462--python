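"""Per-country-per-year crop diversity metrics from harvested-area abundances.

Richness counts crop groups with positive harvested area; Shannon diversity
(natural log) and Pielou evenness are computed on within-country-year area
proportions.  Evenness is undefined for a single-crop assemblage (``ln S = 0``)
and reported as NaN; downstream trend models exclude those country-years.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ValidationError

__all__ = ["richness", "shannon", "pielou", "diversity_table"]


def _positive_areas(areas) -> np.ndarray:
    """Validate an abundance vector and return only the positive entries."""
    if isinstance(areas, Mapping):
        arr = np.asarray(list(areas.values()), dtype=float)
    else:
        arr = np.asarray(areas, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("areas must be a 1-d mapping or vector")
    if arr.size == 0:
        raise EmptyInputError("no area records supplied")
    if np.any(~np.isfinite(arr)):
        raise ValidationError("areas must be finite")
    if np.any(arr < 0):
        raise ValidationError("areas must be non-negative")
    pos = arr[arr > 0]
    if pos.size == 0:
        raise EmptyInputError("no crop with positive area: no cultivation record")
    return pos


def richness(areas) -> int:
    """Number of crop groups with strictly positive harvested area.

    Zero-area entries are absences and do not count.
    """
    return int(_positive_areas(areas).size)


def shannon(areas) -> float:
    """Shannon diversity ``H = -sum(p_i ln p_i)`` in nats.

    Proportions are taken over the positive-area crop groups of a single
    country-year: ``p_i = area_i / sum(area)``.
    """
    pos = _positive_areas(areas)
    p = pos / pos.sum()
    return float(-np.sum(p * np.log(p)))


def pielou(areas) -> float:
    """Pielou evenness ``J = H / ln(S)`` in [0, 1]; NaN when ``S == 1``."""
    pos = _positive_areas(areas)
    s = pos.size
    if s == 1:
        return float("nan")
    p = pos / pos.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


def diversity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Compute S, H, J and total area per (country, year).

    Parameters
    ----------
    records
        Long-format harmonized records with columns
        ``country, year, crop_group, area_ha``.  Zero-area rows are treated
        as absences.

    Returns
    -------
    DataFrame with columns ``country, year, S, H, J, total_area``, one row
    per country-year with at least one positive-area record, sorted by
    country then year.  ``J`` is NaN where ``S == 1``.
    """
    required = {"country", "year", "crop_group", "area_ha"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    if np.any(records["area_ha"].to_numpy(dtype=float) < 0):
        raise ValidationError("areas must be non-negative")

    pos = records[records["area_ha"] > 0]
    rows = []
    for (country, year), grp in pos.groupby(["country", "year"], sort=True):
        areas = grp["area_ha"].to_numpy(dtype=float)
        s = int(areas.size)
        p = areas / areas.sum()
        h = float(-np.sum(p * np.log(p)))
        j = float("nan") if s == 1 else h / np.log(s)
        rows.append(
            {
                "country": country,
                "year": int(year),
                "S": s,
                "H": h,
                "J": j,
                "total_area": float(areas.sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["country", "year", "S", "H", "J", "total_area"]
    )
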