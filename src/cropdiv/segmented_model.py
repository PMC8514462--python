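"""Two-breakpoint piecewise-linear trend fitting for diversity time series.

The response (richness S or evenness J) is modelled as

    y = a + b*t + c*(t - psi1)_+ + d*(t - psi2)_+

so the slope is ``b`` before the first breakpoint ``psi1``, ``b + c`` between
the breakpoints and ``b + c + d`` after ``psi2``.  Breakpoints are estimated
by iterative relinearization: the design is augmented with "gap" indicator
columns and each breakpoint is moved by the ratio of its gap coefficient to
its slope-difference coefficient until the update norm falls below tolerance.
An exhaustive integer-grid search (`grid_oracle`) provides an independent
global-optimum reference for the same objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .exceptions import ValidationError

__all__ = ["SegmentedFit", "fit_linear", "fit_segmented", "grid_oracle"]

#: model degrees of freedom of the segmented fit (3 slope terms + 2 breakpoints)
_DF_MODEL = 5


@dataclass(frozen=True)
class SegmentedFit:
    """Fitted parameters and diagnostics for one series.

    Slopes per segment are ``b``, ``b + c`` and ``b + c + d``; ``psi1`` and
    ``psi2`` are the breakpoint years.  ``converged`` is False when the
    iteration failed, the breakpoints collapsed or left the data range, or a
    segment had insufficient support — ``reason`` then says why.
    """

    a: float
    b: float
    c: float
    d: float
    psi1: float
    psi2: float
    r2: float
    p_value: float
    sse: float
    converged: bool
    n: int
    response_label: str = "S"
    reason: str | None = None
    n_iter: int = 0

    @property
    def slopes(self) -> tuple[float, float, float]:
        return (self.b, self.b + self.c, self.b + self.c + self.d)

    def predict(self, years) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        return (
            self.a
            + self.b * t
            + self.c * np.clip(t - self.psi1, 0.0, None)
            + self.d * np.clip(t - self.psi2, 0.0, None)
        )


def _check_series(years, response, min_n: int):
    t = np.asarray(years, dtype=float)
    y = np.asarray(response, dtype=float)
    if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
        raise ValidationError("years and response must be 1-d vectors of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("years must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValidationError("years and response must be finite")
    if t.size < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {t.size}")
    return t, y


def fit_linear(years, response) -> tuple[float, float, float, float]:
    """Ordinary least squares ``y = a + b*t``.

    Returns ``(a, b, r2, p)`` where ``p`` is the overall model F-test
    p-value (identical to the slope t-test for simple regression).
    """
    t, y = _check_series(years, response, min_n=3)
    if np.ptp(t) == 0:
        raise ValidationError("years are constant: design is rank deficient")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    return float(res.intercept), float(res.slope), r2, float(res.pvalue)


def _piecewise_design(t: np.ndarray, psi1: float, psi2: float) -> np.ndarray:
    return np.column_stack(
        [
            np.ones_like(t),
            t,
            np.clip(t - psi1, 0.0, None),
            np.clip(t - psi2, 0.0, None),
        ]
    )


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _finalize(
    t: np.ndarray,
    y: np.ndarray,
    psi1: float,
    psi2: float,
    converged: bool,
    reason: str | None,
    n_iter: int,
    response_label: str,
    min_segment: int,
) -> SegmentedFit:
    """Refit the continuous piecewise model at fixed breakpoints and attach
    diagnostics."""
    coef, sse = _ols_sse(_piecewise_design(t, psi1, psi2), y)
    n = t.size
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    df_resid = n - (_DF_MODEL + 1)
    if sst > 0 and sse > 0 and df_resid > 0:
        f = ((sst - sse) / _DF_MODEL) / (sse / df_resid)
        p = float(stats.f.sf(f, _DF_MODEL, df_resid))
    elif sst > 0 and sse == 0:
        p = 0.0
    else:
        p = float("nan")
    if converged:
        n_left = int(np.sum(t <= psi1))
        n_mid = int(np.sum((t > psi1) & (t <= psi2)))
        n_right = int(np.sum(t > psi2))
        if min(n_left, n_mid, n_right) < min_segment:
            converged = False
            reason = (
                f"segment support below {min_segment} "
                f"(left={n_left}, mid={n_mid}, right={n_right})"
            )
    return SegmentedFit(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        d=float(coef[3]),
        psi1=float(psi1),
        psi2=float(psi2),
        r2=r2,
        p_value=p,
        sse=sse,
        converged=converged,
        n=n,
        response_label=response_label,
        reason=reason,
        n_iter=n_iter,
    )


def fit_segmented(
    years,
    response,
    init_psi1: float = 1975.0,
    init_psi2: float = 2000.0,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    min_segment: int = 2,
    response_label: str = "S",
) -> SegmentedFit:
    """Fit the two-breakpoint model by iterative relinearization.

    At each iteration the design contains the two hinge columns
    ``(t - psi_k)_+`` and two gap columns ``-I(t > psi_k)``; the breakpoint
    update is ``psi_k += gamma_k / beta_k`` (gap over slope-difference
    coefficient), damped by step halving to stay inside the data range.
    Convergence requires the breakpoint update norm to fall below ``tol``.

    A series shorter than 7 points yields a non-converged result (two
    breakpoints and three slopes cannot be supported); unordered years raise
    :class:`~cropdiv.exceptions.ValidationError`.
    """
    t, y = _check_series(years, response, min_n=3)
    n = t.size
    lo, hi = float(t[0]), float(t[-1])

    if n < 7:
        return _finalize(
            t, y, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3,
            converged=False, reason=f"too few observations (n={n} < 7)",
            n_iter=0, response_label=response_label, min_segment=min_segment,
        )
    if not (lo < init_psi1 < init_psi2 < hi):
        raise ValidationError(
            f"initial breakpoints ({init_psi1}, {init_psi2}) must be ordered "
            f"and strictly inside the data range ({lo}, {hi})"
        )

    eps = 1e-9 * max(1.0, hi - lo)

    def _profile_sse(p: np.ndarray) -> float:
        return _ols_sse(_piecewise_design(t, p[0], p[1]), y)[1]

    psi = np.array([init_psi1, init_psi2], dtype=float)
    cur_sse = _profile_sse(psi)
    converged = False
    reason: str | None = "maximum iterations reached"
    it = 0
    for it in range(1, max_iter + 1):
        hinge = np.clip(t[:, None] - psi[None, :], 0.0, None)
        gap = -(t[:, None] > psi[None, :]).astype(float)
        X = np.column_stack([np.ones(n), t, hinge, gap])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        beta = coef[2:4]
        gamma = coef[4:6]
        if np.any(np.abs(beta) < 1e-12):
            converged = False
            reason = "degenerate slope difference (no detectable breakpoint)"
            break
        step = gamma / beta
        # damp the step until the breakpoints stay ordered inside the range
        # AND the profile SSE does not increase (descent safeguard)
        h = 1.0
        new_psi = psi + step
        new_sse = np.inf
        for _ in range(16):
            if lo + eps < new_psi[0] < new_psi[1] < hi - eps:
                new_sse = _profile_sse(new_psi)
                if new_sse <= cur_sse * (1 + 1e-10) + 1e-12:
                    break
            h *= 0.5
            new_psi = psi + h * step
        else:
            # no admissible descent step left: treat as converged at psi
            converged = True
            reason = None
            break
        if np.max(np.abs(new_psi - psi)) < tol:
            psi = new_psi
            converged = True
            reason = None
            break
        psi, cur_sse = new_psi, new_sse

    if converged:
        # deterministic local polish of the profile SSE: the relinearization
        # step can stall just short of the optimum once updates get damped
        res = minimize(
            _profile_sse, psi, method="Nelder-Mead",
            options={"xatol": tol, "fatol": 1e-12, "maxiter": 400},
        )
        cand = np.asarray(res.x, dtype=float)
        if (
            lo + eps < cand[0] < cand[1] < hi - eps
            and _profile_sse(cand) <= _profile_sse(psi)
        ):
            psi = cand

    return _finalize(
        t, y, psi[0], psi[1], converged, reason, it,
        response_label=response_label, min_segment=min_segment,
    )


def grid_oracle(
    years,
    response,
    *,
    min_segment: int = 2,
    response_label: str = "S",
) -> SegmentedFit:
    """Exhaustive search over ordered integer-year breakpoint pairs.

    Fits the continuous piecewise OLS at every admissible ``(psi1, psi2)``
    integer pair with at least ``min_segment`` observations per segment and
    returns the global SSE minimizer.  Ties break to the earliest pair
    (psi1 first, then psi2).  Used as an independent reference for
    :func:`fit_segmented`; same validation rules apply.
    """
    t, y = _check_series(years, response, min_n=3)
    if t.size < 7:
        lo, hi = float(t[0]), float(t[-1])
        return _finalize(
            t, y, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3,
            converged=False, reason=f"too few observations (n={t.size} < 7)",
            n_iter=0, response_label=response_label, min_segment=min_segment,
        )

    candidates = []
    for p1 in range(math.floor(t[0]), math.ceil(t[-1]) + 1):
        if np.sum(t <= p1) < min_segment:
            continue
        for p2 in range(p1 + 1, math.ceil(t[-1]) + 1):
            if np.sum((t > p1) & (t <= p2)) < min_segment:
                continue
            if np.sum(t > p2) < min_segment:
                continue
            candidates.append((p1, p2))
    if not candidates:
        return _finalize(
            t, y, float(t[0]) + 1, float(t[-1]) - 1,
            converged=False, reason="no admissible integer breakpoint pair",
            n_iter=0, response_label=response_label, min_segment=min_segment,
        )

    best = None
    best_sse = np.inf
    for p1, p2 in candidates:  # ordered: earliest pair wins ties
        _, sse = _ols_sse(_piecewise_design(t, float(p1), float(p2)), y)
        if best is None or sse < best_sse - 1e-12 * (1.0 + abs(best_sse)):
            best_sse = sse
            best = (p1, p2)
    fit = _finalize(
        t, y, float(best[0]), float(best[1]), True, None, 0,
        response_label=response_label, min_segment=min_segment,
    )
    return replace(fit, n_iter=len(candidates))
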