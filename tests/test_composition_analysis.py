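import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cropdiv.composition_analysis import (
    bray_curtis_matrix,
    classical_mds,
    community_matrix,
    composition_terms,
    n_pairs,
    nmds,
    per_group_dispersion,
    permanova,
    stress1,
)
from cropdiv.exceptions import ValidationError


def oneway_permanova_oracle(D, groups):
    """Textbook one-way PERMANOVA pseudo-F from a distance matrix.

    SS_total = sum of squared distances / n; SS_within = per-group sums of
    squared within-group distances over group size.  Fully independent of
    the package's Gower-trace route.
    """
    D = np.asarray(D)
    groups = np.asarray(groups)
    n = D.shape[0]
    levels = np.unique(groups)
    a = levels.size
    ss_total = np.sum(np.triu(D, 1) ** 2) / n
    ss_within = 0.0
    for lev in levels:
        idx = np.where(groups == lev)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += np.sum(np.triu(sub, 1) ** 2) / idx.size
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among, ss_within, ss_total


class TestPairs:
    def test_closed_form(self):
        assert n_pairs(4) == 6
        assert n_pairs(10854) == 58899231

    def test_matches_condensed_storage(self, rng):
        X = rng.random((17, 4))
        assert bray_curtis_matrix(X).size == n_pairs(17)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d[0] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d = bray_curtis_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d[0] == pytest.approx(1.0)

    def test_hand_computed(self):
        # |2-1| + |1-1| over (2+1) + (1+1) = 1/5
        d = bray_curtis_matrix(np.array([[2.0, 1.0], [1.0, 1.0]]))
        assert d[0] == pytest.approx(0.2, abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis_matrix(np.array([[1.0, 1.0], [0.0, 0.0]]))

    def test_range_and_symmetry(self, rng):
        X = rng.random((9, 6)) + 0.01
        D = squareform(bray_curtis_matrix(X))
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.allclose(np.diag(D), 0)


class TestCommunityMatrix:
    def test_pivot_shape_and_zero_fill(self, fixture_records):
        mat = community_matrix(fixture_records)
        assert mat.shape == (50, 6)  # 5 countries x 10 years
        assert (mat.to_numpy().sum(axis=1) > 0).all()

    def test_absent_columns_kept_as_zero(self):
        records = pd.DataFrame(
            {
                "country": ["A", "A", "B"],
                "year": [2000, 2000, 2000],
                "crop_group": ["x", "y", "x"],
                "area_ha": [1.0, 2.0, 3.0],
            }
        )
        mat = community_matrix(records)
        assert mat.loc[("B", 2000), "y"] == 0.0


class TestNMDS:
    def test_planar_configuration_low_stress(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        d = pdist(square)
        _, stress = nmds(d, k=2, n_starts=2, seed=0)
        assert stress < 0.01

    def test_duplicated_points_coincide(self):
        X = np.array([[1.0, 2.0, 0.5]] * 2 + [[5.0, 1.0, 2.0]] + [[0.1, 3.0, 1.0]])
        d = bray_curtis_matrix(X)
        coords, _ = nmds(d, k=2, n_starts=2, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-3

    def test_seed_reproducibility(self, rng):
        X = rng.random((20, 5))
        d = bray_curtis_matrix(X)
        c1, s1 = nmds(d, seed=99)
        c2, s2 = nmds(d, seed=99)
        assert s1 == s2
        assert np.array_equal(c1, c2)

    def test_stress_not_worse_than_classical_init(self, rng):
        X = rng.random((15, 4))
        d = bray_curtis_matrix(X)
        _, stress = nmds(d, seed=0)
        assert stress <= stress1(d, classical_mds(d, 2)) + 1e-9

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            nmds(pdist(np.eye(3)), k=3)


class TestPermanova:
    def test_two_separated_clusters_high_r2(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.05, (8, 3)), rng.normal(5, 0.05, (8, 3))]
        )
        D = squareform(pdist(X))
        groups = np.repeat(["a", "b"], 8)
        dummies = (groups[:, None] == np.unique(groups)[None, 1:]).astype(float)
        table = permanova(D, [("group", dummies)], n_perm=99, seed=0)
        assert table.loc["group", "r2"] > 0.9
        assert table.loc["group", "p"] == pytest.approx(0.01)

    def test_pseudo_f_matches_enumeration_oracle(self, rng):
        X = rng.random((6, 4))
        D = squareform(pdist(X))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        dummies = (groups[:, None] == np.array([["b"]])).astype(float)
        table = permanova(D, [("group", dummies)], n_perm=999, seed=1)
        f_oracle, ss_among, ss_within, ss_total = oneway_permanova_oracle(D, groups)
        assert table.loc["group", "F"] == pytest.approx(f_oracle, rel=1e-9)
        assert table.loc["group", "SS"] == pytest.approx(ss_among, rel=1e-9)
        assert table.loc["Total", "SS"] == pytest.approx(ss_total, rel=1e-9)
        # exact p by full enumeration of the 20 label assignments
        fs = []
        for pos in itertools.combinations(range(6), 3):
            lab = np.full(6, "b")
            lab[list(pos)] = "a"
            fs.append(oneway_permanova_oracle(D, lab)[0])
        p_exact = float(np.mean(np.asarray(fs) >= f_oracle - 1e-12))
        assert abs(table.loc["group", "p"] - p_exact) <= 0.05

    def test_ss_decomposition_conserved(self, rng):
        X = rng.random((12, 5))
        d = bray_curtis_matrix(X)
        country = np.repeat(["a", "b", "c"], 4)
        year = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        table = permanova(d, composition_terms(country, year), n_perm=19, seed=0)
        parts = table.loc[["year", "country", "year:country", "Residuals"], "SS"].sum()
        assert parts == pytest.approx(table.loc["Total", "SS"], rel=1e-9)
        r2 = table.loc[["year", "country", "year:country", "Residuals"], "r2"].sum()
        assert r2 == pytest.approx(1.0, rel=1e-9)

    def test_year_has_one_df(self, rng):
        X = rng.random((12, 5))
        d = bray_curtis_matrix(X)
        country = np.repeat(["a", "b", "c"], 4)
        year = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        table = permanova(d, composition_terms(country, year), n_perm=19, seed=0)
        assert table.loc["year", "df"] == 1
        assert table.loc["country", "df"] == 2

    def test_sample_order_invariance(self, rng):
        X = rng.random((12, 5))
        country = np.repeat(["a", "b", "c"], 4)
        year = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        D = squareform(bray_curtis_matrix(X))
        t1 = permanova(D, composition_terms(country, year), n_perm=9, seed=0)
        perm = rng.permutation(12)
        t2 = permanova(
            D[np.ix_(perm, perm)],
            composition_terms(country[perm], year[perm]),
            n_perm=9,
            seed=0,
        )
        for term in ("year", "country", "year:country"):
            assert t1.loc[term, "SS"] == pytest.approx(t2.loc[term, "SS"], rel=1e-9)

    def test_p_resolution_with_99_perms(self, rng):
        X = rng.random((10, 4))
        d = bray_curtis_matrix(X)
        groups = np.repeat(["a", "b"], 5)
        dummies = (groups[:, None] == np.array([["b"]])).astype(float)
        table = permanova(d, [("group", dummies)], n_perm=99, seed=3)
        p = table.loc["group", "p"]
        assert round(p * 100) == pytest.approx(p * 100, abs=1e-9)
        assert 0.01 <= p <= 1.0

    def test_confounded_design_rejected(self):
        D = squareform(pdist(np.arange(6.0)[:, None]))
        x = np.arange(6.0)[:, None]
        with pytest.raises(ValidationError):
            permanova(D, [("a", x), ("b", 2 * x)], n_perm=9)


class TestDispersion:
    def test_tight_group_smaller_dispersion(self, rng):
        coords = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(0, 2.0, (5, 2))])
        labels = np.repeat(["tight", "wide"], 5)
        disp = per_group_dispersion(coords, labels)
        assert disp["tight"] < disp["wide"]
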