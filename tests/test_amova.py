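"""AMOVA sums of squares, variance components, Phi and permutation tests."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from epiclover.data import BinaryMarkerMatrix, DistanceMatrix, ValidationError
from epiclover.amova import (
    Amova,
    amova_coefficients,
    pairwise_phi_pt,
    squared_euclidean_distances,
)

from conftest import random_binary_matrix, two_habitat_samples


def oracle_two_level(d, pop_of_idx, grp_of_pop):
    """Direct-sum oracle: the defining SS/MS/component formulas computed
    independently, loop by loop, from the distance matrix."""
    N = len(pop_of_idx)
    pops = sorted(set(pop_of_idx))
    groups = sorted(set(grp_of_pop.values()))
    ss_total = sum(d[i][j] for i in range(N) for j in range(i + 1, N)) / N
    ss_w = 0.0
    for p in pops:
        idx = [i for i, q in enumerate(pop_of_idx) if q == p]
        ss_w += sum(d[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_wg = 0.0
    for g in groups:
        idx = [i for i, q in enumerate(pop_of_idx) if grp_of_pop[q] == g]
        ss_wg += sum(d[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_ap = ss_wg - ss_w
    ss_ag = ss_total - ss_wg
    G, K = len(groups), len(pops)
    df = (G - 1, K - G, N - K)
    ms = (ss_ag / df[0], ss_ap / df[1], ss_w / df[2])
    sizes = {p: pop_of_idx.count(p) for p in pops}
    sg = {g: sum(sizes[p] ** 2 for p in pops if grp_of_pop[p] == g)
          / sum(sizes[p] for p in pops if grp_of_pop[p] == g) for g in groups}
    n1 = (N - sum(sg.values())) / (K - G)
    n2 = (sum(sg.values()) - sum(v**2 for v in sizes.values()) / N) / (G - 1)
    Ng = {g: sum(sizes[p] for p in pops if grp_of_pop[p] == g) for g in groups}
    n3 = (N - sum(v**2 for v in Ng.values()) / N) / (G - 1)
    vc = ms[2]
    vb = (ms[1] - vc) / n1
    va = (ms[0] - vc - n2 * vb) / n3
    return {"SS": (ss_ag, ss_ap, ss_w), "df": df, "MS": ms, "var": (va, vb, vc)}


def structured_design(rng, n_per_pop=2, n_markers=4):
    """2 groups x 2 populations per group with visible group structure."""
    base = {"g0p0": 0.9, "g0p1": 0.8, "g1p0": 0.2, "g1p1": 0.1}
    samples = two_habitat_samples(2, 2, n_per_pop)
    values = np.array([
        (rng.random(n_markers) < base[s.population_id]).astype(int) for s in samples
    ])
    m = BinaryMarkerMatrix([s.sample_id for s in samples],
                           [f"m{j}" for j in range(n_markers)], values)
    return m, samples


class TestSquaredEuclideanDistances:
    def test_identical_rows_zero(self):
        m = BinaryMarkerMatrix(["a", "b"], ["m0", "m1"], [[1, 0], [1, 0]])
        assert squared_euclidean_distances(m).values[0, 1] == 0.0

    def test_counts_differing_markers(self):
        m = BinaryMarkerMatrix(["a", "b"], ["m0", "m1", "m2"], [[1, 0, 1], [0, 0, 1]])
        assert squared_euclidean_distances(m).values[0, 1] == 1.0

    def test_complementary_rows_give_length(self):
        m = BinaryMarkerMatrix(["a", "b"], [f"m{j}" for j in range(7)],
                               [[1] * 7, [0] * 7])
        assert squared_euclidean_distances(m).values[0, 1] == 7.0


class TestCoefficients:
    def test_reference_design_closed_form(self):
        n1, n2, n3 = amova_coefficients([16] * 10, [0] * 5 + [1] * 5)
        assert (n1, n2, n3) == (16.0, 16.0, 80.0)

    def test_equal_sizes_reduce_to_n(self):
        n1, n2, n3 = amova_coefficients([4] * 6, [0, 0, 0, 1, 1, 1])
        assert n1 == pytest.approx(4.0)
        assert n2 == pytest.approx(4.0)
        assert n3 == pytest.approx(12.0)


class TestTwoLevelAmova:
    def test_reference_design_degrees_of_freedom(self):
        samples = two_habitat_samples(2, 5, 16)
        rng = np.random.default_rng(0)
        values = (rng.random((160, 20)) < 0.5).astype(int)
        m = BinaryMarkerMatrix([s.sample_id for s in samples],
                               [f"m{j}" for j in range(20)], values)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=0)
        assert tuple(res.table["df"]) == (1, 8, 150)

    def test_components_match_direct_sum_oracle(self, rng):
        m, samples = structured_design(rng)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=0)
        d = squared_euclidean_distances(m)
        pop_of_idx = [s.population_id for s in samples]
        grp_of_pop = {s.population_id: s.habitat for s in samples}
        exp = oracle_two_level(d.values.tolist(), pop_of_idx, grp_of_pop)
        np.testing.assert_allclose(res.table["SS"], exp["SS"], atol=1e-9)
        np.testing.assert_allclose(res.table["MS"], exp["MS"], atol=1e-9)
        assert tuple(res.table["df"]) == exp["df"]
        np.testing.assert_allclose(
            [res.raw_components[k] for k in
             ("among_groups", "among_populations", "within_populations")],
            exp["var"], atol=1e-9)

    def test_oracle_agreement_on_random_small_datasets(self, rng):
        for _ in range(10):
            m, samples = structured_design(rng, n_per_pop=2, n_markers=6)
            res = Amova.from_marker_matrix(m, samples).fit(n_permutations=0)
            exp = oracle_two_level(
                squared_euclidean_distances(m).values.tolist(),
                [s.population_id for s in samples],
                {s.population_id: s.habitat for s in samples})
            np.testing.assert_allclose(res.table["SS"], exp["SS"], atol=1e-9)

    def test_ss_additivity(self, rng):
        m = random_binary_matrix(rng, n=24, m=15)
        samples = two_habitat_samples(2, 3, 4)
        m = BinaryMarkerMatrix([s.sample_id for s in samples], m.marker_ids, m.values)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=0)
        assert res.table["SS"].sum() == pytest.approx(res.ss_total, abs=1e-9)

    def test_percentages_sum_to_100(self, small_study):
        res = Amova.from_marker_matrix(small_study.aflp, small_study.samples).fit(
            n_permutations=0)
        assert res.table["pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert (res.table["est_var"] >= 0).all()

    def test_identical_individuals_degenerate(self):
        samples = two_habitat_samples(2, 2, 2)
        m = BinaryMarkerMatrix([s.sample_id for s in samples], ["m0", "m1"],
                               np.ones((8, 2), dtype=int))
        with pytest.warns(UserWarning, match="total variance is zero"):
            res = Amova.from_marker_matrix(m, samples).fit(n_permutations=0)
        assert res.phi == {"phi_RT": 0.0, "phi_PR": 0.0, "phi_PT": 0.0}
        assert res.table["SS"].sum() == 0.0

    def test_singleton_population_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], squareform([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="singleton"):
            Amova(d, populations=["p1", "p1", "p2"])

    def test_population_spanning_two_groups_impossible_by_construction(self):
        # group membership is keyed by population, so a split population
        # cannot even be expressed; missing mappings are rejected
        d = DistanceMatrix(["a", "b", "c", "d"], squareform([1.0] * 6))
        with pytest.raises(ValidationError, match="without group"):
            Amova(d, populations=["p1", "p1", "p2", "p2"], groups={"p1": "G1"})


class TestPermutationTests:
    def test_structured_data_significant(self, rng):
        m, samples = structured_design(rng, n_per_pop=8, n_markers=30)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=199, seed=1)
        assert res.p_values["phi_PT"] <= 0.05

    def test_null_phi_near_zero_gives_large_p(self, rng):
        samples = two_habitat_samples(2, 3, 6)
        values = (rng.random((36, 30)) < 0.5).astype(int)
        m = BinaryMarkerMatrix([s.sample_id for s in samples],
                               [f"m{j}" for j in range(30)], values)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=199, seed=2)
        # exchangeable data: no permutation statistic should dominate
        assert res.p_values["phi_PT"] >= 0.05

    def test_p_bounded_below_by_estimator(self, rng):
        m, samples = structured_design(rng, n_per_pop=6, n_markers=40)
        res = Amova.from_marker_matrix(m, samples).fit(n_permutations=99, seed=3)
        for p in res.p_values.values():
            assert 1 / 100 <= p <= 1.0

    def test_p_invariant_to_row_order(self, rng):
        m, samples = structured_design(rng, n_per_pop=6, n_markers=30)
        perm = rng.permutation(len(samples))
        samples2 = [samples[i] for i in perm]
        m2 = m.reindex_samples([s.sample_id for s in samples2])
        r1 = Amova.from_marker_matrix(m, samples).fit(n_permutations=499, seed=4)
        r2 = Amova.from_marker_matrix(m2, samples2).fit(n_permutations=499, seed=4)
        assert r1.phi_pt == pytest.approx(r2.phi_pt, abs=1e-12)
        # permutation p agrees within Monte-Carlo error
        se = np.sqrt(0.25 / 500)
        assert abs(r1.p_values["phi_PT"] - r2.p_values["phi_PT"]) <= 4 * se

    def test_zero_permutations_requested_rejected_for_tests(self, rng):
        m, samples = structured_design(rng)
        model = Amova.from_marker_matrix(m, samples)
        with pytest.raises(ValidationError):
            model.fit(n_permutations=-1)


class TestPairwisePhiPT:
    def test_identical_populations_zero(self):
        values = [[1, 0, 1], [0, 1, 1]] * 2
        m = BinaryMarkerMatrix([f"s{i}" for i in range(4)],
                               ["m0", "m1", "m2"], values)
        d = squared_euclidean_distances(m)
        phi, _ = pairwise_phi_pt(d, ["p1", "p1", "p2", "p2"], n_permutations=0)
        assert phi.values[0, 1] == 0.0

    def test_fixed_complementary_populations_one(self):
        values = [[1, 1, 1]] * 3 + [[0, 0, 0]] * 3
        m = BinaryMarkerMatrix([f"s{i}" for i in range(6)],
                               ["m0", "m1", "m2"], values)
        d = squared_euclidean_distances(m)
        phi, _ = pairwise_phi_pt(d, ["p1"] * 3 + ["p2"] * 3, n_permutations=0)
        assert phi.values[0, 1] == pytest.approx(1.0)

    def test_ten_populations_give_45_pairs(self, default_study):
        d = squared_euclidean_distances(default_study.aflp)
        pop_of = {s.sample_id: s.population_id for s in default_study.samples}
        phi, p = pairwise_phi_pt(d, pop_of, n_permutations=0)
        assert phi.n == 10
        off = phi.condensed()
        assert len(off) == 45
        assert (off >= 0).all()
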