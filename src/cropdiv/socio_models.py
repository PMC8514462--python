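"""HDI mixed models with nested continent/region random effects.

Each change indicator is predicted from a fixed intercept + HDI slope with
random intercepts for continent and for region nested within continent
(REML).  Explained variance is partitioned into four proportions that sum
to one: the fixed part (variance of the fixed-effect predictions, the
marginal-R2 convention), the two random variance components, and the
residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .exceptions import ValidationError
from .indicators import DEFAULT_LOG_OFFSET, choose_distribution

__all__ = [
    "MixedModelResult",
    "transform_indicator",
    "fit_hdi_mixed_model",
    "variance_components",
]


@dataclass(frozen=True)
class MixedModelResult:
    metric: str
    indicator: str
    transform: str
    intercept: float
    intercept_se: float
    hdi_slope: float
    hdi_se: float
    hdi_p: float
    prop_fixed: float
    prop_continent: float
    prop_region: float
    prop_unexplained: float
    n: int
    boundary: bool  # True when a variance component sits at zero


def transform_indicator(
    values,
    indicator: str,
    metric: str = "S",
    offset: float = DEFAULT_LOG_OFFSET,
) -> tuple[np.ndarray, str]:
    """Identity-vs-log transform chosen by the normal/lognormal AIC rule.

    When the lognormal candidate wins and any value is <= 0, the configured
    positive offset is added before taking logs; the returned label records
    exactly what was applied (``"identity"``, ``"log"`` or ``"log(x+10)"``).
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValidationError("values must be finite")
    dist, shift = choose_distribution(x, offset=offset)
    if dist == "normal":
        return x.copy(), "identity"
    if shift > 0:
        return np.log(x + shift), f"log(x+{shift:g})"
    return np.log(x), "log"


def variance_components(
    fixed_predictions,
    var_continent: float,
    var_region: float,
    var_residual: float,
) -> tuple[float, float, float, float]:
    """Proportions (fixed, continent, region, unexplained) summing to one.

    The fixed share is the variance of the fixed-effect predictions over
    the total of all four sources.
    """
    var_fixed = float(np.var(np.asarray(fixed_predictions, dtype=float), ddof=1))
    parts = np.array([var_fixed, var_continent, var_region, var_residual], dtype=float)
    if np.any(parts < 0):
        raise ValidationError("variance components must be non-negative")
    total = parts.sum()
    if total <= 0:
        raise ValidationError("zero total variance: degenerate model")
    props = parts / total
    return tuple(float(v) for v in props)


def fit_hdi_mixed_model(
    data: pd.DataFrame,
    response: str = "value",
    metric: str = "S",
    indicator: str = "1",
    transform_label: str = "identity",
) -> MixedModelResult:
    """REML linear mixed model ``response ~ hdi`` with nested random
    intercepts for continent and region-within-continent.

    ``data`` needs columns ``hdi, continent, region`` plus the response;
    incomplete rows are dropped.  Requires >= 2 continents.  A variance
    component estimated at (or numerically below) zero is kept and flagged
    via ``boundary`` rather than treated as a failure.
    """
    cols = [response, "hdi", "continent", "region"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data missing columns: {missing}")
    d = data[cols].dropna().copy()
    if d["continent"].nunique() < 2:
        raise ValidationError("need >= 2 continents")
    for cont, grp in d.groupby("continent"):
        if grp["region"].nunique() < 1:
            raise ValidationError(f"continent {cont} has no region")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"{response} ~ hdi",
            d,
            groups=d["continent"],
            re_formula="1",
            vc_formula={"region": "0 + C(region)"},
        )
        # the default optimizer stalls on boundary (zero-variance) fits;
        # walk through optimizers until one converges
        res = None
        for method in ("lbfgs", "bfgs", "powell"):
            candidate = model.fit(reml=True, method=method, maxiter=2000)
            if candidate.converged:
                res = candidate
                break
        if res is None:
            res = candidate

    var_continent = float(res.cov_re.iloc[0, 0])
    var_region = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    fixed_pred = res.model.exog @ res.fe_params
    props = variance_components(fixed_pred, max(var_continent, 0.0),
                                max(var_region, 0.0), var_resid)
    boundary = min(var_continent, var_region) < 1e-8
    return MixedModelResult(
        metric=metric,
        indicator=indicator,
        transform=transform_label,
        intercept=float(res.fe_params.iloc[0]),
        intercept_se=float(res.bse_fe.iloc[0]),
        hdi_slope=float(res.fe_params.iloc[1]),
        hdi_se=float(res.bse_fe.iloc[1]),
        hdi_p=float(res.pvalues.iloc[1]),
        prop_fixed=props[0],
        prop_continent=props[1],
        prop_region=props[2],
        prop_unexplained=props[3],
        n=int(len(d)),
        boundary=bool(boundary),
    )
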