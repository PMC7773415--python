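"""Tests for similarity index, muscle invariants, clustering and the
shared-DOF / shared-function pair tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from polymuscle import (
    PolynomialModel,
    SIGNATURE_ORDER,
    invariant_distances,
    invariant_vector,
    shared_dof_test,
    shared_function_test,
    similarity_index,
)
from polymuscle.invariants import (
    _difference_population,
    pool_phalangeal,
)
from polymuscle.terms import structure as mk

structures = st.sets(
    st.lists(st.integers(1, 3), max_size=4).map(lambda x: tuple(sorted(x))),
    max_size=8,
).map(frozenset)


class TestSimilarityIndex:
    def test_identical_structures(self, ecu_moment_arm):
        assert similarity_index(
            ecu_moment_arm.structure, ecu_moment_arm.structure
        ) == 100.0

    def test_disjoint_structures(self):
        assert similarity_index(mk([(1,), (1, 1)]), mk([(2,), (2, 2)])) == 0.0

    def test_half_shared(self):
        A = mk([(), (1,), (1, 1)])
        B = mk([(), (1,), (2,)])
        assert similarity_index(A, B) == pytest.approx(50.0)

    def test_both_empty_defined_as_identical(self):
        assert similarity_index(frozenset(), frozenset()) == 100.0

    @given(structures, structures)
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_bounds(self, A, B):
        si = similarity_index(A, B)
        assert si == similarity_index(B, A)
        assert 0.0 <= si <= 100.0
        assert similarity_index(A, A) == 100.0


class TestInvariantVector:
    def test_signature_axes_are_the_18_partitions(self):
        assert len(SIGNATURE_ORDER) == 18
        assert len(set(SIGNATURE_ORDER)) == 18

    def test_worked_example_lands_on_v9_v12_v16(self):
        # L = C1 x1 x2^2 + C2 x1^2 x2 + C3 x1^3 + C4 x1 + C5 x2 + C6
        L = PolynomialModel(2, {
            (1, 2, 2): 1.5, (1, 1, 2): -2.0, (1, 1, 1): 3.0,
            (1,): 0.5, (2,): 1.0, (): 9.0,
        })
        v = invariant_vector(L)
        nonzero = set(np.flatnonzero(v) + 1)  # 1-based axes
        assert nonzero == {9, 12, 16}
        raw = v * np.linalg.norm([1.5 + 2.0, 0.5 + 1.0, 3.0])
        assert raw[8] == pytest.approx(3.5)   # |C1| + |C2|
        assert raw[11] == pytest.approx(1.5)  # |C4| + |C5|
        assert raw[15] == pytest.approx(3.0)  # |C3|

    def test_unit_norm_and_sign_invariance(self):
        L = PolynomialModel(2, {(1,): 2.0, (1, 2): -3.0, (): 5.0})
        v = invariant_vector(L)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        flipped = PolynomialModel(2, {(1,): -2.0, (1, 2): 3.0, (): 5.0})
        assert np.allclose(v, invariant_vector(flipped))

    def test_scale_invariance(self):
        L = PolynomialModel(3, {(1,): 2.0, (2, 3): 1.0, (1, 1, 1): 0.5})
        scaled = PolynomialModel(3, {t: 13.7 * c
                                     for t, c in L.coefficients.items()})
        assert np.allclose(invariant_vector(L), invariant_vector(scaled))

    def test_zero_polynomial_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            v = invariant_vector(PolynomialModel(2, {(): 4.0}))
        assert np.all(v == 0)
        assert any("zero" in r.message for r in caplog.records)


class TestInvariantDistances:
    def _vectors(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        return {f"m{i}": rng.dirichlet(np.ones(18)) for i in range(n)}

    def test_matrix_symmetric_zero_diagonal(self):
        geom = invariant_distances(self._vectors())
        D = geom.distance_matrix
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_identical_vectors_merge_first(self):
        v = np.zeros(18)
        v[0] = 1.0
        rng = np.random.default_rng(1)
        vectors = {"a": v, "b": v.copy(),
                   "c": rng.dirichlet(np.ones(18)),
                   "d": rng.dirichlet(np.ones(18))}
        geom = invariant_distances(vectors)
        assert geom.distance_matrix[0, 1] == 0.0
        first = set(geom.linkage[0, :2].astype(int))
        assert first == {0, 1}

    def test_planted_clusters_split_at_root(self):
        rng = np.random.default_rng(2)
        vectors = {}
        for i in range(4):  # mass on the linear-term axis
            v = np.abs(rng.normal(0, 0.02, 18))
            v[SIGNATURE_ORDER.index((1,))] = 1.0
            vectors[f"lin{i}"] = v / np.linalg.norm(v)
        for i in range(4):  # mass on the quadratic-term axis
            v = np.abs(rng.normal(0, 0.02, 18))
            v[SIGNATURE_ORDER.index((2,))] = 1.0
            vectors[f"quad{i}"] = v / np.linalg.norm(v)
        geom = invariant_distances(vectors)
        labels = fcluster(geom.linkage, t=2, criterion="maxclust")
        lin = {labels[i] for i, k in enumerate(geom.labels)
               if k.startswith("lin")}
        quad = {labels[i] for i, k in enumerate(geom.labels)
                if k.startswith("quad")}
        assert len(lin) == 1 and len(quad) == 1 and lin != quad

    def test_explained_variance_sane(self):
        geom = invariant_distances(self._vectors(3, 8))
        e1, e2 = geom.explained_variance
        assert e1 >= e2 >= 0.0
        assert e1 + e2 <= 1.0 + 1e-12


def _planted_world(effect=True, seed=0):
    """Muscles on two DOFs; sharing dof 'A' goes with a common signature
    family when ``effect`` is True."""
    rng = np.random.default_rng(seed)
    vectors, incidence = {}, {}
    for i in range(6):
        v = np.abs(rng.normal(0, 0.05, 18))
        axis = (1,) if (effect and i < 3) else (2,)
        v[SIGNATURE_ORDER.index(axis)] = 1.0
        vectors[f"m{i}"] = v / np.linalg.norm(v)
        incidence[f"m{i}"] = ("A",) if i < 3 else ("B",)
    # one bridging muscle on both DOFs keeps every DOF testable
    v = np.abs(rng.normal(0, 0.05, 18))
    v[SIGNATURE_ORDER.index((1,) if effect else (2,))] = 1.0
    vectors["bridge"] = v / np.linalg.norm(v)
    incidence["bridge"] = ("A", "B")
    return vectors, incidence


class TestSharedDofTest:
    def test_identical_invariants_give_null_result(self):
        v = np.zeros(18)
        v[0] = 1.0
        vectors = {f"m{i}": v.copy() for i in range(6)}
        incidence = {f"m{i}": ("A",) if i < 3 else ("B",) for i in range(6)}
        incidence["m0"] = ("A", "B")
        res = shared_dof_test(vectors, incidence)
        assert res.median_difference == 0.0
        assert res.sign_test_p > 0.05

    def test_planted_shared_dof_effect_detected(self):
        vectors, incidence = _planted_world(effect=True)
        res = shared_dof_test(vectors, incidence)
        assert res.median_difference < 0
        assert res.sign_test_p < 0.01

    def test_difference_population_antisymmetric_under_group_swap(self):
        vectors, _ = _planted_world(effect=True)
        names = sorted(vectors)
        wp = [(names[0], names[1]), (names[2], names[3])]
        op = [(names[0], names[4]), (names[1], names[5])]
        fwd = _difference_population(wp, op, vectors)
        # swapping the group roles negates each retained difference
        rev = _difference_population(op, wp, vectors)
        assert sorted(np.round(fwd, 12)) == sorted(np.round([-x for x in rev], 12))

    def test_single_usable_dof_rejected(self):
        vectors, _ = _planted_world()
        with pytest.raises(ValueError):
            shared_dof_test(vectors, {m: ("A",) for m in vectors})

    def test_phalangeal_pooling(self):
        assert pool_phalangeal("ra_mcp3_f_e") == "ra_mcp_f_e"
        assert pool_phalangeal("ra_dip5_f_e") == "ra_dip_f_e"
        assert pool_phalangeal("ra_wr_s_p") == "ra_wr_s_p"
        assert pool_phalangeal("ra_mcp1_f_e") == "ra_mcp1_f_e"  # thumb stays


class TestSharedFunctionTest:
    def test_planted_category_effect_detected(self):
        rng = np.random.default_rng(7)
        vectors, incidence, cats = {}, {}, {}
        for i in range(10):
            v = np.abs(rng.normal(0, 0.05, 18))
            axis = (1,) if i % 2 == 0 else (3,)
            v[SIGNATURE_ORDER.index(axis)] = 1.0
            vectors[f"m{i}"] = v / np.linalg.norm(v)
            incidence[f"m{i}"] = ("A",)
            cats[f"m{i}"] = "even" if i % 2 == 0 else "odd"
        res = shared_function_test(vectors, cats, incidence)
        assert res.median_difference < 0
        assert res.sign_test_p < 0.01

    def test_single_category_rejected(self):
        vectors, incidence = _planted_world()
        cats = {m: "only" for m in vectors}
        with pytest.raises(ValueError):
            shared_function_test(vectors, cats, incidence)

    def test_invariant_under_muscle_reordering(self):
        vectors, incidence = _planted_world(effect=True)
        cats = {m: ("c1" if m in ("m0", "m1", "m2", "bridge") else "c2")
                for m in vectors}
        res1 = shared_function_test(vectors, cats, incidence)
        shuffled = dict(reversed(list(vectors.items())))
        res2 = shared_function_test(shuffled, cats, incidence)
        assert res1.median_difference == pytest.approx(res2.median_difference)
        assert res1.mannwhitney_u == pytest.approx(res2.mannwhitney_u)

    def test_missing_category_rejected(self):
        vectors, incidence = _planted_world()
        with pytest.raises(ValueError):
            shared_function_test(vectors, {"m0": "c"}, incidence)
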