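"""K2P distances, great-circle distances, and the Mantel test."""

import math

import numpy as np
import pytest

from polymito import popgen
from polymito import synthetic_data as synth


class TestK2p:
    def test_identical_is_zero(self):
        assert popgen.k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition_closed_form(self):
        # P = 1/4, Q = 0 -> d = -0.5 ln(1/2)
        assert popgen.k2p("AAAA", "GAAA") == pytest.approx(-0.5 * math.log(0.5))

    def test_saturation_is_missing(self):
        assert math.isnan(popgen.k2p("AAAA", "TTTT"))

    def test_pairwise_deletion_of_n_sites(self):
        # the N column is dropped, leaving P = 1/3
        with_n = popgen.k2p("AANA", "GANA")
        assert with_n == pytest.approx(popgen.k2p("AAA", "GAA"))

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            popgen.k2p("AAA", "AAAA")

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            popgen.k2p("NNN", "AAA")

    def test_zero_iff_identical_at_comparable_sites(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=100))
            assert popgen.k2p(s, s) == 0.0
            i = int(rng.integers(100))
            mutated = s[:i] + {"A": "G", "C": "T", "G": "A", "T": "C"}[s[i]] + s[i + 1 :]
            assert popgen.k2p(s, mutated) > 0.0


class TestHaversine:
    def test_zero_and_antipodal(self):
        p = popgen.GeoPoint(12.0, 34.0)
        assert popgen.haversine_km(p, p) == 0.0
        assert popgen.haversine_km(
            popgen.GeoPoint(0, 0), popgen.GeoPoint(0, 180)
        ) == pytest.approx(math.pi * 6371.0, rel=1e-6)

    def test_one_degree_of_latitude(self):
        d = popgen.haversine_km(popgen.GeoPoint(0, 0), popgen.GeoPoint(1, 0))
        assert d == pytest.approx(6371.0 * math.pi / 180, rel=1e-6)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            popgen.haversine_km(popgen.GeoPoint(91, 0), popgen.GeoPoint(0, 0))


class TestDistanceMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            popgen.DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            popgen.DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


def _random_dm(rng, labels):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.random(len(iu[0]))
    m[iu] = vals
    return popgen.DistanceMatrix(labels, m + m.T)


class TestMantel:
    def test_affine_relation_gives_r_one_and_smallest_p(self):
        rng = np.random.default_rng(1)
        labels = tuple("abcdefg")
        d1 = _random_dm(rng, labels)
        d2 = popgen.DistanceMatrix(labels, 2.0 * d1.values)
        res = popgen.mantel(d1, d2, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000, abs=2e-3)

    def test_label_alignment(self):
        rng = np.random.default_rng(2)
        labels = tuple("abcde")
        d1 = _random_dm(rng, labels)
        perm = ("c", "a", "e", "b", "d")
        idx = [labels.index(l) for l in perm]
        d2 = popgen.DistanceMatrix(perm, d1.values[np.ix_(idx, idx)])
        res = popgen.mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        labels = tuple("abcdef")
        d1, d2 = _random_dm(rng, labels), _random_dm(rng, labels)
        r1 = popgen.mantel(d1, d2, n_perm=499, seed=11)
        r2 = popgen.mantel(d1, d2, n_perm=499, seed=11)
        assert r1 == r2

    def test_constant_matrix_rejected(self):
        labels = tuple("abcd")
        ones = np.ones((4, 4)) - np.eye(4)
        const = popgen.DistanceMatrix(labels, ones)
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="constant"):
            popgen.mantel(const, _random_dm(rng, labels), n_perm=99)

    def test_matches_scikit_bio(self):
        """Cross-check r and p against the independent scikit-bio implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        labels = tuple("abcdefgh")
        d1, d2 = _random_dm(rng, labels), _random_dm(rng, labels)
        mine = popgen.mantel(d1, d2, n_perm=9999, seed=0)
        ref_r, ref_p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, labels),
            skbio_distance.DistanceMatrix(d2.values, labels),
            method="pearson",
            permutations=9999,
            alternative="greater",
        )
        assert mine.r == pytest.approx(ref_r, abs=1e-12)
        assert mine.p_value == pytest.approx(ref_p, abs=0.02)

    def test_ibd_scenario_detected(self):
        seqs, coords, _ = synth.make_ibd(n_demes=10, slope=5e-5, seed=42)
        pts = [
            (row["label"], popgen.GeoPoint(row["lat"], row["lon"]))
            for _, row in coords.iterrows()
        ]
        res = popgen.mantel(
            popgen.k2p_matrix(seqs), popgen.geographic_matrix(pts), n_perm=999, seed=42
        )
        assert res.r > 0.5 and res.p_value < 0.05
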