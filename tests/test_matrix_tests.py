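"""Geographic/habitat matrices and Mantel / partial Mantel / MMRR."""

import itertools
import math

import numpy as np
import pytest

from epiclover.data import DistanceMatrix, SiteRecord, ValidationError
from epiclover.matrix_tests import (
    EARTH_RADIUS_KM,
    Mmrr,
    geographic_distance_matrix,
    habitat_dissimilarity_matrix,
    mantel,
    partial_mantel,
)

from conftest import random_distance_matrix


def sites_grid(habitats):
    return [SiteRecord(f"p{i}", h, 48.0 + 0.05 * i, 9.0 + 0.1 * (i % 3))
            for i, h in enumerate(habitats)]


def pearson_upper(A, B):
    a, b = A.condensed(), B.condensed()
    return np.corrcoef(a, b)[0, 1]


def mantel_exact_oracle(A, B):
    """Brute-force enumeration of all n! relabelings of A."""
    n = A.n
    iu = np.triu_indices(n, k=1)
    b = B.condensed()
    r_obs = pearson_upper(A, B)
    count = total = 0
    for p in itertools.permutations(range(n)):
        perm = np.asarray(p)
        r = np.corrcoef(A.values[np.ix_(perm, perm)][iu], b)[0, 1]
        count += r >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


class TestGeographicDistances:
    def test_identical_points_zero(self):
        s = SiteRecord("a", "CG", 48.0, 9.0)
        t = SiteRecord("b", "CG", 48.0, 9.0)
        assert geographic_distance_matrix([s, t]).values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        s = SiteRecord("a", "CG", 48.0, 9.0)
        t = SiteRecord("b", "CG", 49.0, 9.0)
        d = geographic_distance_matrix([s, t]).values[0, 1]
        assert d == pytest.approx(111.195, abs=5e-4)

    def test_symmetry_and_triangle_inequality(self, rng):
        sites = [SiteRecord(f"p{i}", "CG",
                            float(rng.uniform(-60, 60)), float(rng.uniform(-120, 120)))
                 for i in range(8)]
        d = geographic_distance_matrix(sites).values
        np.testing.assert_allclose(d, d.T)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestHabitatDissimilarity:
    def test_coding(self):
        d = habitat_dissimilarity_matrix(sites_grid(["CG", "OM", "CG"]))
        assert d.values[0, 1] == 1.0  # CG vs OM
        assert d.values[0, 2] == 0.0  # CG vs CG

    def test_five_vs_five_has_25_cross_pairs(self):
        d = habitat_dissimilarity_matrix(sites_grid(["CG"] * 5 + ["OM"] * 5))
        assert d.condensed().sum() == 25.0
        assert len(d.condensed()) == 45


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        A = random_distance_matrix(rng, n=8)
        res = mantel(A, A, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self, rng):
        A = random_distance_matrix(rng, n=6)
        C = DistanceMatrix(A.labels, 1.0 - np.eye(6), name="habitat")
        C = DistanceMatrix(A.labels, np.where(np.eye(6, dtype=bool), 0.0, 2.5), name="const")
        with pytest.raises(ValidationError, match="const"):
            mantel(A, C, n_perm=9, seed=0)

    def test_exact_p_matches_enumeration_at_n4(self, rng):
        for _ in range(5):
            A = random_distance_matrix(rng, n=4)
            B = random_distance_matrix(rng, n=4)
            B = DistanceMatrix(A.labels, B.values)
            res = mantel(A, B, method="exact")
            r_exp, p_exp = mantel_exact_oracle(A, B)
            assert res.r == pytest.approx(r_exp)
            assert res.p == pytest.approx(p_exp)
            assert res.n_perm == 24

    def test_sampled_p_converges_to_exact(self, rng):
        A = random_distance_matrix(rng, n=5)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=5).values)
        exact = mantel(A, B, method="exact")
        sampled = mantel(A, B, n_perm=4999, seed=5)
        assert abs(sampled.p - exact.p) <= 4 * math.sqrt(0.25 / 5000)

    def test_r_symmetric_in_arguments(self, rng):
        A = random_distance_matrix(rng, n=9)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=9).values)
        assert mantel(A, B, n_perm=9, seed=0).r == pytest.approx(
            mantel(B, A, n_perm=9, seed=0).r)

    def test_invariant_under_simultaneous_relabeling(self, rng):
        A = random_distance_matrix(rng, n=7)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=7).values)
        perm = rng.permutation(7)
        labels = [A.labels[i] for i in perm]
        A2 = DistanceMatrix(labels, A.permuted(perm))
        B2 = DistanceMatrix(labels, B.permuted(perm))
        assert mantel(A2, B2, n_perm=9, seed=0).r == pytest.approx(
            mantel(A, B, n_perm=9, seed=0).r)

    def test_cross_check_against_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        A = random_distance_matrix(rng, n=10)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=10).values)
        ours = mantel(A, B, n_perm=999, seed=3)
        ref_r, ref_p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(A.values, A.labels),
            skbio_distance.DistanceMatrix(B.values, B.labels),
            method="pearson", permutations=999, alternative="greater")
        assert ours.r == pytest.approx(ref_r, abs=1e-12)
        assert abs(ours.p - ref_p) <= 4 * math.sqrt(0.25 / 1000)


class TestPartialMantel:
    def test_reduces_to_simple_when_c_uncorrelated(self, rng):
        # C orthogonal in expectation: average over draws
        A = random_distance_matrix(rng, n=12)
        B = DistanceMatrix(A.labels, A.values + random_distance_matrix(rng, n=12).values)
        diffs = []
        for _ in range(20):
            C = DistanceMatrix(A.labels, random_distance_matrix(rng, n=12).values)
            res = partial_mantel(A, B, C, n_perm=9, seed=0)
            diffs.append(res.r - mantel(A, B, n_perm=9, seed=0).r)
        assert abs(np.mean(diffs)) < 0.05

    def test_identical_matrices_partial_r_is_one(self, rng):
        A = random_distance_matrix(rng, n=8)
        B = DistanceMatrix(A.labels, A.values.copy())
        C = DistanceMatrix(A.labels, random_distance_matrix(rng, n=8).values)
        res = partial_mantel(A, B, C, n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_degenerate_conditioning_rejected(self, rng):
        A = random_distance_matrix(rng, n=6)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=6).values)
        C = DistanceMatrix(A.labels, 2.0 * A.values)
        with pytest.raises(ValidationError, match="degenerate"):
            partial_mantel(A, B, C, n_perm=9, seed=0)

    def test_exact_enumeration_at_n4(self, rng):
        A = random_distance_matrix(rng, n=4)
        B = DistanceMatrix(A.labels, random_distance_matrix(rng, n=4).values)
        C = DistanceMatrix(A.labels, random_distance_matrix(rng, n=4).values)
        res = partial_mantel(A, B, C, method="exact")
        # oracle: enumerate all 24 relabelings of A
        iu = np.triu_indices(4, k=1)
        b, c = B.condensed(), C.condensed()
        r_bc = np.corrcoef(b, c)[0, 1]

        def partial_r(a):
            r_ab = np.corrcoef(a, b)[0, 1]
            r_ac = np.corrcoef(a, c)[0, 1]
            return (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))

        r_obs = partial_r(A.condensed())
        vals = [partial_r(A.values[np.ix_(p, p)][iu])
                for p in map(np.asarray, itertools.permutations(range(4)))]
        p_exp = sum(v >= r_obs - 1e-12 for v in vals) / 24
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(p_exp)


class TestMmrr:
    def test_perfect_single_predictor(self, rng):
        Y = random_distance_matrix(rng, n=8)
        res = Mmrr(Y, {"self": Y}).fit(n_permutations=99, seed=0)
        assert res.coefficients.loc["self", "coefficient"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_coefficient_equals_mantel_r(self, rng):
        for _ in range(5):
            Y = random_distance_matrix(rng, n=9)
            X = DistanceMatrix(Y.labels, random_distance_matrix(rng, n=9).values)
            res = Mmrr(Y, {"x": X}).fit(n_permutations=9, seed=0)
            assert res.coefficients.loc["x", "coefficient"] == pytest.approx(
                mantel(Y, X, n_perm=9, seed=0).r, abs=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        Y = random_distance_matrix(rng, n=8)
        X = DistanceMatrix(Y.labels, random_distance_matrix(rng, n=8).values, name="geo")
        X2 = DistanceMatrix(Y.labels, 3.0 * X.values, name="geo_km")
        with pytest.raises(ValidationError, match="geo"):
            Mmrr(Y, [X, X2])

    def test_structured_response_detected(self, rng):
        X = random_distance_matrix(rng, n=10)
        noise = random_distance_matrix(rng, n=10).values
        Y = DistanceMatrix(X.labels, X.values * 3.0 + 0.1 * noise)
        X2 = DistanceMatrix(X.labels, random_distance_matrix(rng, n=10).values)
        res = Mmrr(Y, {"signal": X, "noise": X2}).fit(n_permutations=199, seed=1)
        assert res.coefficients.loc["signal", "p"] <= 0.05
        assert res.f_p <= 0.05
        assert res.r_squared > 0.5

    def test_needs_at_least_five_sites(self, rng):
        Y = random_distance_matrix(rng, n=4)
        with pytest.raises(ValidationError, match="n >= 5"):
            Mmrr(Y, [DistanceMatrix(Y.labels, Y.values.copy())])
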