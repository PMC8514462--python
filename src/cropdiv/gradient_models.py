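"""Latitudinal richness gradients and auxiliary country-area regressions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ValidationError

__all__ = ["LatGradientFit", "fit_latitude_gradient", "peak_latitude", "area_regression"]

#: quadratic coefficients closer to zero than this have no interior maximum
_BETA2_TOL = 1e-12


@dataclass(frozen=True)
class LatGradientFit:
    """Quadratic regression of richness on absolute latitude for one year."""

    year: int
    beta0: float
    beta1: float
    beta2: float
    se0: float
    se1: float
    se2: float
    r2: float
    p_value: float
    peak_latitude: float | None
    n: int


def peak_latitude(beta1: float, beta2: float) -> float:
    """Vertex of the fitted parabola, ``-beta1 / (2 beta2)``.

    Only defined for a concave fit (``beta2 < 0``); otherwise the model has
    no interior richness maximum and a ValidationError is raised.
    """
    if not beta2 < -_BETA2_TOL:
        raise ValidationError(
            f"beta2={beta2:g} is not negative: no interior maximum"
        )
    return -beta1 / (2.0 * beta2)


def fit_latitude_gradient(latitude_abs, richness, year: int) -> LatGradientFit:
    """OLS of richness on |latitude| and |latitude|^2 (raw polynomial basis).

    Callers are responsible for restricting input to countries observed in
    both comparison years.  Requires >= 10 countries and >= 3 distinct
    latitudes.
    """
    lat = np.asarray(latitude_abs, dtype=float)
    s = np.asarray(richness, dtype=float)
    if lat.size != s.size:
        raise ValidationError("latitude and richness must have equal length")
    if lat.size < 10:
        raise ValidationError(f"need >= 10 countries, got {lat.size}")
    if np.any(lat < 0) or np.any(lat > 90):
        raise ValidationError("absolute latitude must be in [0, 90]")
    if np.unique(lat).size < 3:
        raise ValidationError("need >= 3 distinct latitudes (rank deficiency)")

    X = sm.add_constant(np.column_stack([lat, lat**2]))
    res = sm.OLS(s, X).fit()
    b0, b1, b2 = (float(v) for v in res.params)
    peak = None
    if b2 < -_BETA2_TOL:
        peak = -b1 / (2.0 * b2)
    return LatGradientFit(
        year=int(year),
        beta0=b0, beta1=b1, beta2=b2,
        se0=float(res.bse[0]), se1=float(res.bse[1]), se2=float(res.bse[2]),
        r2=float(res.rsquared), p_value=float(res.f_pvalue),
        peak_latitude=peak, n=int(lat.size),
    )


def area_regression(indicators: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Simple OLS of each indicator on each country-area measure.

    ``indicators`` has a country index and one column per indicator;
    ``areas`` has a country index and one column per area measure (total
    and/or cultivated area, ha).  Returns a diagnostics table with one row
    per indicator x measure combination (r2, p, n); combinations with fewer
    than 3 paired finite values or a constant regressor are skipped with a
    warning and reported as NaN.
    """
    rows = []
    for ind_name in indicators.columns:
        for area_name in areas.columns:
            joined = pd.concat(
                [indicators[ind_name], areas[area_name]], axis=1, join="inner"
            ).dropna()
            y = joined.iloc[:, 0].to_numpy(dtype=float)
            x = joined.iloc[:, 1].to_numpy(dtype=float)
            if y.size < 3 or np.ptp(x) == 0:
                warnings.warn(
                    f"area regression {ind_name} ~ {area_name} skipped "
                    f"(n={y.size}, constant regressor={bool(y.size and np.ptp(x) == 0)})",
                    stacklevel=2,
                )
                rows.append(
                    {"indicator": ind_name, "area_measure": area_name,
                     "r2": np.nan, "p": np.nan, "n": int(y.size)}
                )
                continue
            res = sm.OLS(y, sm.add_constant(x)).fit()
            rows.append(
                {"indicator": ind_name, "area_measure": area_name,
                 "r2": float(res.rsquared), "p": float(res.f_pvalue),
                 "n": int(y.size)}
            )
    return pd.DataFrame(rows)
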