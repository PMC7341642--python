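"""Jaccard/geographic distance matrices, Mantel test, Mantel correlogram."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mycocheck import (DistanceMatrix, geo_distance_matrix, jaccard_matrix,
                       mantel_correlogram, mantel_test)
from mycocheck.errors import AlignmentError, MycocheckError
from mycocheck.spatial import haversine_km

set_strategy = st.sets(st.integers(0, 15), min_size=1)


class TestJaccardMatrix:
    def test_identical_sets_have_zero_dissimilarity(self):
        dm = jaccard_matrix({"A": {1, 2}, "B": {1, 2}})
        assert dm.values[0, 1] == 0.0

    def test_disjoint_sets_have_dissimilarity_one(self):
        dm = jaccard_matrix({"A": {1, 2}, "B": {3}})
        assert dm.values[0, 1] == 1.0

    def test_hand_counted_value(self):
        dm = jaccard_matrix({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(MycocheckError, match="B"):
            jaccard_matrix({"A": {1}, "B": set()})

    @given(a=set_strategy, b=set_strategy, c=set_strategy)
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        dm = jaccard_matrix({"A": a, "B": b, "C": c})
        d = dm.values
        assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12
        assert d[1, 2] <= d[1, 0] + d[0, 2] + 1e-12


class TestGeoDistance:
    def test_analytic_reference_points(self):
        assert haversine_km(0, 0, 0, 0) == 0.0
        quarter = 2 * math.pi * 6371 / 4
        assert haversine_km(0, 0, 0, 90) == pytest.approx(quarter, rel=1e-9)
        assert haversine_km(0, 0, 0, 180) == pytest.approx(2 * quarter, rel=1e-9)
        assert haversine_km(90, 0, -90, 0) == pytest.approx(2 * quarter, rel=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            geo_distance_matrix({"A": (0, 200), "B": (0, 0)})

    def test_matrix_symmetric_zero_diagonal(self):
        dm = geo_distance_matrix({"A": (5, 0), "B": (10, 3), "C": (-4, 7)})
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


def _random_distance_matrix(rng, labels):
    n = len(labels)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return DistanceMatrix(list(labels), v)


class TestMantel:
    def test_affine_transform_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        d1 = _random_distance_matrix(rng, "ABCDE")
        d2 = DistanceMatrix(d1.labels, 2.0 * d1.values + 3.0 * (d1.values > 0))
        res = mantel_test(d1, d2, n_perm=99, seed=1)
        assert res.r_M == pytest.approx(1.0)

    def test_label_mismatch_raises(self):
        rng = np.random.default_rng(1)
        d1 = _random_distance_matrix(rng, "ABC")
        d2 = _random_distance_matrix(rng, "ABD")
        with pytest.raises(AlignmentError):
            mantel_test(d1, d2, n_perm=99)

    def test_reordered_labels_are_aligned(self):
        rng = np.random.default_rng(2)
        d1 = _random_distance_matrix(rng, "ABCD")
        d2 = _random_distance_matrix(rng, "ABCD")
        res1 = mantel_test(d1, d2, n_perm=99, seed=3)
        res2 = mantel_test(d1, d2.reorder(["D", "B", "A", "C"]).reorder(d1.labels),
                           n_perm=99, seed=3)
        assert res1.r_M == pytest.approx(res2.r_M)

    def test_common_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        d1 = _random_distance_matrix(rng, "ABCDE")
        d2 = _random_distance_matrix(rng, "ABCDE")
        perm = [3, 1, 4, 0, 2]
        relabel = [d1.labels[i] for i in perm]
        p1 = DistanceMatrix(list("ABCDE"), d1.values[np.ix_(perm, perm)])
        p2 = DistanceMatrix(list("ABCDE"), d2.values[np.ix_(perm, perm)])
        assert mantel_test(d1, d2, n_perm=99, seed=0).r_M == pytest.approx(
            mantel_test(p1, p2, n_perm=99, seed=0).r_M)

    def test_zero_variance_degenerate_contract(self):
        d1 = DistanceMatrix(list("ABC"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        rng = np.random.default_rng(4)
        d2 = _random_distance_matrix(rng, "ABC")
        res = mantel_test(d1, d2, n_perm=99)
        assert res.r_M == 0.0 and res.p_perm == 1.0 and res.degenerate

    def test_seed_reproducibility_and_p_resolution(self):
        rng = np.random.default_rng(5)
        d1 = _random_distance_matrix(rng, "ABCDEF")
        d2 = _random_distance_matrix(rng, "ABCDEF")
        r1 = mantel_test(d1, d2, n_perm=199, seed=7)
        r2 = mantel_test(d1, d2, n_perm=199, seed=7)
        assert (r1.r_M, r1.p_perm) == (r2.r_M, r2.p_perm)
        assert (r1.p_perm * 200) == pytest.approx(round(r1.p_perm * 200))

    def test_exhaustive_p_matches_enumeration_oracle(self):
        """All 23 non-identity relabelings of a 4-label matrix, enumerated independently."""
        rng = np.random.default_rng(6)
        d1 = _random_distance_matrix(rng, "ABCD")
        d2 = _random_distance_matrix(rng, "ABCD")
        res = mantel_test(d1, d2, exhaustive=True, tail="greater")
        idx = np.tril_indices(4, k=-1)
        x = d1.values[idx]
        r_obs = np.corrcoef(x, d2.values[idx])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            if perm == (0, 1, 2, 3):
                continue
            permuted = d2.values[np.ix_(perm, perm)]
            if np.corrcoef(x, permuted[idx])[0, 1] >= r_obs - 1e-12:
                count += 1
        assert res.n_perm == 23
        assert res.p_perm == pytest.approx((1 + count) / 24)

    def test_statistic_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel
        rng = np.random.default_rng(8)
        d1 = _random_distance_matrix(rng, "ABCDEF")
        d2 = _random_distance_matrix(rng, "ABCDEF")
        r_skbio, _, _ = mantel(SkbioDM(d1.values, d1.labels),
                               SkbioDM(d2.values, d2.labels),
                               method="pearson", permutations=0)
        assert mantel_test(d1, d2, n_perm=99, seed=0).r_M == pytest.approx(
            float(r_skbio))


class TestCorrelogram:
    def test_zero_variance_composition_gives_null_classes(self):
        n = 6
        v = np.ones((n, n)) * 0.4
        np.fill_diagonal(v, 0)
        d1 = DistanceMatrix([f"c{i}" for i in range(n)], v, "jaccard_dissimilarity")
        coords = {f"c{i}": (float(i), float(2 * i % 5)) for i in range(n)}
        dg = geo_distance_matrix(coords)
        cg = mantel_correlogram(d1, dg, n_classes=3, n_perm=99, seed=0)
        for cls in cg.classes:
            assert cls.r_M == 0.0 and cls.p == 1.0

    def test_classes_equal_direct_mantel_against_membership(self):
        rng = np.random.default_rng(9)
        labels = list("ABCDE")
        d1 = _random_distance_matrix(rng, labels)
        coords = {l: (float(rng.uniform(0, 20)), float(rng.uniform(0, 20)))
                  for l in labels}
        dg = geo_distance_matrix(coords)
        cg = mantel_correlogram(d1, dg, n_classes=2, n_perm=199, seed=5)
        n = len(labels)
        i_idx, j_idx = np.tril_indices(n, k=-1)
        dist = dg.values[i_idx, j_idx]
        edges = np.linspace(dist.min(), dist.max(), 3)
        for c, cls in enumerate(cg.classes):
            in_class = (dist >= edges[c]) & (dist < edges[c + 1])
            if c == 1:
                in_class |= np.isclose(dist, edges[-1])
            member = np.zeros((n, n))
            member[i_idx[in_class], j_idx[in_class]] = 1
            member += member.T
            direct = mantel_test(d1, DistanceMatrix(labels, member),
                                 n_perm=199, seed=5, tail="two-sided")
            assert cls.r_M == pytest.approx(direct.r_M)
            assert cls.p == pytest.approx(direct.p_perm)

    def test_progressive_correction_never_below_raw(self):
        rng = np.random.default_rng(10)
        d1 = _random_distance_matrix(rng, "ABCDEFGH")
        coords = {l: (float(rng.uniform(0, 30)), float(rng.uniform(0, 30)))
                  for l in d1.labels}
        cg = mantel_correlogram(d1, geo_distance_matrix(coords), n_perm=99, seed=1)
        for cls in cg.classes:
            assert cls.p_corrected >= cls.p - 1e-12

    def test_detects_distance_decay_composition(self):
        """Nearby communities share more species: first class r < 0, corrected p small."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            n, n_species = 20, 150
            coords = rng.uniform(0, 30, size=(n, 2))
            homes = rng.uniform(0, 30, size=(n_species, 2))
            sets = {}
            for i in range(n):
                d = np.hypot(*(homes - coords[i]).T)
                sets[f"c{i:02d}"] = set(np.nonzero(d < 9.0)[0]) | {int(rng.integers(n_species))}
            dj = jaccard_matrix(sets)
            dg = geo_distance_matrix({k: tuple(coords[i]) for i, k in
                                      enumerate(sorted(sets))})
            cg = mantel_correlogram(dj, dg, n_classes=5, n_perm=99,
                                    seed=int(rng.integers(2**31)))
            first = cg.classes[0]
            if first.r_M < 0 and first.p_corrected < 0.05:
                hits += 1
        assert hits > n_rep / 2
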