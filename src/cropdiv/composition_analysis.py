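"""Multivariate composition change: Bray-Curtis distances, NMDS, PERMANOVA.

Country-by-year samples form a community matrix with harvested area as the
abundance proxy.  Pairwise Bray-Curtis dissimilarities feed a non-metric
multidimensional scaling (Kruskal stress-1 with monotone regression) and a
sequential permutational MANOVA with terms entered in the order
year (numeric, 1 df) -> country -> year x country, significance assessed by
free permutation of sample labels with the count-based estimator
``(b + 1) / (m + 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .exceptions import ValidationError

__all__ = [
    "n_pairs",
    "community_matrix",
    "bray_curtis_matrix",
    "classical_mds",
    "stress1",
    "nmds",
    "composition_terms",
    "permanova",
    "per_group_dispersion",
]


def n_pairs(n: int) -> int:
    """Number of unique unordered pairs stored in a condensed distance
    structure for ``n`` samples: ``n (n - 1) / 2``."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    return n * (n - 1) // 2


def community_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format records into a (country, year) x crop_group matrix.

    Cells are harvested area in ha; crop groups absent from a sample are
    zeros.  Every row must have a positive total.
    """
    mat = records.pivot_table(
        index=["country", "year"],
        columns="crop_group",
        values="area_ha",
        aggfunc="sum",
        fill_value=0.0,
    ).sort_index()
    totals = mat.to_numpy().sum(axis=1)
    if np.any(totals <= 0):
        bad = mat.index[totals <= 0].tolist()
        raise ValidationError(f"samples with zero total area: {bad[:5]}")
    return mat


def bray_curtis_matrix(mat) -> np.ndarray:
    """All pairwise Bray-Curtis dissimilarities, condensed form.

    ``BC_jk = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)``; the output stores
    exactly ``n_pairs(n)`` values.
    """
    X = np.asarray(mat, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-d matrix with at least 2 rows")
    if np.any(X < 0):
        raise ValidationError("abundances must be non-negative")
    if np.any(X.sum(axis=1) == 0):
        raise ValidationError("rows of all zeros are not valid communities")
    return pdist(X, metric="braycurtis")


def _as_square(dist) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim == 1:
        D = squareform(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance input must be condensed or square")
    return D


def classical_mds(dist, k: int = 2) -> np.ndarray:
    """Classical (metric) MDS coordinates from the Gower-centred matrix."""
    D = _as_square(dist)
    n = D.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n}")
    G = _gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def stress1(dist, coords) -> float:
    """Kruskal stress-1 of a configuration against the dissimilarities.

    Disparities come from isotonic (monotone) regression of configuration
    distances on the rank order of the dissimilarities.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    conf = pdist(np.asarray(coords, dtype=float))
    order = np.argsort(d, kind="stable")
    iso = IsotonicRegression(increasing=True)
    disp = np.empty_like(conf)
    disp[order] = iso.fit_transform(np.arange(d.size), conf[order])
    denom = float(np.sum(conf**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((conf - disp) ** 2) / denom))


def nmds(
    dist,
    k: int = 2,
    n_starts: int = 4,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS minimizing Kruskal stress-1.

    One start is initialized from classical MDS, the remaining
    ``n_starts - 1`` from seeded random configurations; the configuration
    with the lowest stress (recomputed with :func:`stress1` for
    comparability) is returned as ``(coordinates, stress)``.
    """
    D = _as_square(dist)
    n = D.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n}")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")

    inits: list[np.ndarray | None] = [classical_mds(D, k)]
    rng = np.random.default_rng(seed)
    best_coords = None
    best_stress = np.inf
    for i in range(n_starts):
        if i == 0:
            init = inits[0]
        else:
            init = rng.standard_normal((n, k)) * np.mean(D)
        coords, _ = smacof(
            D,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            normalized_stress=True,
            random_state=0,
        )
        s = stress1(D, coords)
        if s < best_stress:
            best_stress = s
            best_coords = coords
    return best_coords, float(best_stress)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    row = A.mean(axis=0, keepdims=True)
    col = A.mean(axis=1, keepdims=True)
    return A - row - col + A.mean()


def composition_terms(country, year) -> list[tuple[str, np.ndarray]]:
    """Design blocks for the year -> country -> year x country decomposition.

    Year enters as a single numeric covariate (1 df); country as drop-first
    dummy columns; the interaction as year x country dummies.
    """
    country = np.asarray(country)
    yr = np.asarray(year, dtype=float)
    if country.size != yr.size:
        raise ValidationError("country and year must have equal length")
    levels = np.unique(country)
    if levels.size < 2:
        raise ValidationError("need at least 2 countries")
    yc = yr - yr.mean()
    dummies = (country[:, None] == levels[None, 1:]).astype(float)
    inter = yc[:, None] * dummies
    return [
        ("year", yc[:, None]),
        ("country", dummies),
        ("year:country", inter),
    ]


def permanova(
    dist,
    terms: list[tuple[str, np.ndarray]],
    n_perm: int = 99,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (entry-order) permutational MANOVA on a distance matrix.

    Each term's sum of squares is the increment in ``tr(H G)`` when its
    design block is appended to the model, where ``G`` is the Gower-centred
    inner-product matrix of the squared distances.  Pseudo-F uses the full
    model's residual mean square.  P-values come from ``n_perm`` free
    permutations of the sample labels, ``p = (b + 1) / (n_perm + 1)``.

    Returns a table with one row per term plus Residuals and Total and
    columns ``df, SS, MS, F, r2, p``.
    """
    D = _as_square(dist)
    n = D.shape[0]
    blocks = [np.ones((n, 1))] + [np.atleast_2d(np.asarray(x, dtype=float)) for _, x in terms]
    names = [name for name, _ in terms]
    for b in blocks:
        if b.shape[0] != n:
            raise ValidationError("design rows must match number of samples")
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("confounded factors: design is rank deficient")
    dfs = [b.shape[1] for b in blocks[1:]]
    rank_full = X.shape[1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    G = _gower_center(D)
    ss_total = float(np.trace(G))
    bounds = np.cumsum([1] + dfs)  # column index after each term block

    def _stats(Xmat: np.ndarray) -> tuple[np.ndarray, float]:
        Q, _ = np.linalg.qr(Xmat)
        contrib = np.einsum("ij,ij->j", Q, G @ Q)
        cums = np.add.accumulate(contrib)
        tr_at = cums[bounds - 1]  # tr(P G) after intercept, then after each term
        ss_terms = np.diff(tr_at)
        ss_res = ss_total - tr_at[-1]
        ms_res = ss_res / df_res
        f = (ss_terms / np.asarray(dfs)) / ms_res
        return f, ss_res

    f_obs, ss_res = _stats(X)
    # recover term SS from F for reporting (avoids recomputation drift)
    ms_res = ss_res / df_res
    ss_terms = f_obs * np.asarray(dfs) * ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = _stats(X[perm])
        exceed += f_perm >= f_obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for name, df_t, ss_t, f_t, p_t in zip(names, dfs, ss_terms, f_obs, p):
        rows.append(
            {"term": name, "df": df_t, "SS": ss_t, "MS": ss_t / df_t,
             "F": f_t, "r2": ss_t / ss_total, "p": p_t}
        )
    rows.append(
        {"term": "Residuals", "df": df_res, "SS": ss_res, "MS": ms_res,
         "F": np.nan, "r2": ss_res / ss_total, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "MS": np.nan,
         "F": np.nan, "r2": 1.0, "p": np.nan}
    )
    return pd.DataFrame(rows).set_index("term")


def per_group_dispersion(coords, labels) -> pd.Series:
    """Mean Euclidean distance to the group centroid in ordination space.

    Used to expose per-year dispersion of the NMDS configuration (a
    shrinking value over time indicates increasing compositional
    similarity among countries).
    """
    C = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        pts = C[labels == lab]
        centroid = pts.mean(axis=0)
        out[lab] = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    return pd.Series(out, name="dispersion")
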