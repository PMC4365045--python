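"""Diversity indices, Phi_ST AMOVA distance, and classical MDS."""

import numpy as np
import pytest

from mitophylogeo.nomenclature import HaplotypeProfile, parse_motif, restrict_range
from mitophylogeo.popgen import (
    DistanceMatrix,
    PopulationSet,
    classical_mds,
    diversity,
    fst_matrix,
    haplotype_distance,
    pairwise_phist,
)

from conftest import random_profile


def hvs1(motif: str, sid: str = "x") -> HaplotypeProfile:
    return restrict_range(parse_motif(motif, sid), 16024, 16365)


class TestHaplotypeDistance:
    def test_counts_each_differing_site_once(self):
        a = hvs1("T16126C-A16309G")
        b = hvs1("T16126C-A16309T")   # same site, different allele: 1 step
        c = hvs1("T16126C")
        assert haplotype_distance(a, b) == 1
        assert haplotype_distance(a, c) == 1
        assert haplotype_distance(a, a) == 0

    def test_brute_force_per_position_state_comparison(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = random_profile(rng, n=int(rng.integers(0, 10)), sample_id="a")
            b = random_profile(rng, n=int(rng.integers(0, 10)), sample_id="b")

            # oracle: materialise full per-position states
            state_a = {v.position: v.alt for v in a.variants}
            state_b = {v.position: v.alt for v in b.variants}
            diff = sum(
                1
                for pos in set(state_a) | set(state_b)
                if state_a.get(pos) != state_b.get(pos)
            )
            assert haplotype_distance(a, b) == diff


class TestDiversity:
    def test_identical_haplotypes(self):
        pop = PopulationSet("p", [hvs1("T16126C", f"s{i}") for i in range(4)])
        r = diversity(pop)
        assert (r.HD, r.M, r.pi) == (0.0, 0.0, 0.0)

    def test_two_haplotypes_one_difference(self):
        pop = PopulationSet("p", [hvs1("T16126C", "a"), hvs1("T16126C-A16309G", "b")])
        r = diversity(pop)
        assert r.HD == pytest.approx(1.0)
        assert r.M == pytest.approx(1.0)
        assert r.L == 342
        assert r.pi == pytest.approx(1 / 342)

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(12)
        profiles = []
        for i in range(12):
            toks = sorted(
                {f"T{p}C" for p in rng.choice(np.arange(16024, 16366), size=rng.integers(1, 6), replace=False)},
                key=lambda t: int(t[1:-1]),
            )
            profiles.append(hvs1("-".join(toks), f"s{i}"))
        pop = PopulationSet("p", profiles)
        r = diversity(pop)

        n = len(profiles)
        counts = {}
        for p in profiles:
            counts["-".join(p.tokens())] = counts.get("-".join(p.tokens()), 0) + 1
        hd = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))
        dsum, npairs = 0, 0
        for i in range(n):
            for j in range(i + 1, n):
                dsum += haplotype_distance(profiles[i], profiles[j])
                npairs += 1
        assert r.HD == pytest.approx(hd)
        assert r.M == pytest.approx(dsum / npairs)
        assert r.pi * r.L == pytest.approx(r.M)

    def test_singleton_population_rejected(self):
        with pytest.raises(ValueError):
            diversity(PopulationSet("p", [hvs1("T16126C")]))


class TestPhiST:
    def test_identical_populations_zero(self):
        a = PopulationSet("a", [hvs1("T16126C", "a1"), hvs1("A16309G", "a2")])
        b = PopulationSet("b", [hvs1("T16126C", "b1"), hvs1("A16309G", "b2")])
        assert pairwise_phist(a, b) == 0.0

    def test_complete_fixation_one(self):
        a = PopulationSet("a", [hvs1("T16126C", f"a{i}") for i in range(3)])
        b = PopulationSet("b", [hvs1("A16309G-T16356C", f"b{i}") for i in range(3)])
        assert pairwise_phist(a, b) == pytest.approx(1.0)

    def test_all_identical_everywhere_degenerate_zero(self):
        a = PopulationSet("a", [hvs1("T16126C", f"a{i}") for i in range(2)])
        b = PopulationSet("b", [hvs1("T16126C", f"b{i}") for i in range(2)])
        assert pairwise_phist(a, b) == 0.0

    def test_monotone_in_divergence(self):
        """Phi_ST grows as the two populations' motifs diverge further."""
        rng = np.random.default_rng(21)
        values = []
        shared = "T16126C"
        for extra in (0, 2, 4):
            a_members, b_members = [], []
            pos_pool = list(range(16030, 16360, 7))
            rng.shuffle(pos_pool)
            b_private = "-".join(f"T{p}C" for p in sorted(pos_pool[:extra]))
            for i in range(6):
                a_members.append(hvs1(shared, f"a{i}"))
                motif = shared + ("-" + b_private if b_private else "")
                b_members.append(hvs1(motif, f"b{i}"))
            # sprinkle one private variant into each pop so they are not fixed
            a_members[0] = hvs1(shared + "-A16290G", "a0")
            b_members[0] = hvs1(shared + ("-" + b_private if b_private else "") + "-A16291G", "b0")
            values.append(
                pairwise_phist(
                    PopulationSet("a", a_members), PopulationSet("b", b_members)
                )
            )
        assert values[0] <= values[1] <= values[2]
        assert values[2] > 0.5

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(33)
        a_prof = [random_profile(rng, 5, f"a{i}") for i in range(4)]
        b_prof = [random_profile(rng, 5, f"b{i}") for i in range(4)]
        v1 = pairwise_phist(PopulationSet("a", a_prof), PopulationSet("b", b_prof))
        perm = [a_prof[i] for i in (2, 0, 3, 1)]
        v2 = pairwise_phist(PopulationSet("a", perm), PopulationSet("b", b_prof))
        assert v1 == pytest.approx(v2)


class TestFstMatrix:
    def _pops(self, rng, k, n=4):
        return [
            PopulationSet(f"p{j}", [random_profile(rng, 4, f"p{j}s{i}") for i in range(n)])
            for j in range(k)
        ]

    def test_three_copies_zero_matrix(self):
        profiles = [hvs1("T16126C", "a"), hvs1("A16309G", "b")]
        pops = [
            PopulationSet(f"p{i}", [hvs1("T16126C", f"{i}a"), hvs1("A16309G", f"{i}b")])
            for i in range(3)
        ]
        m = fst_matrix(pops)
        assert np.allclose(m.values, 0)

    def test_entries_match_independent_pairwise_calls(self):
        rng = np.random.default_rng(40)
        pops = self._pops(rng, 5)
        m = fst_matrix(pops)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    pairwise_phist(pops[i], pops[j])
                )

    def test_permutation_consistency(self):
        rng = np.random.default_rng(41)
        pops = self._pops(rng, 4)
        m = fst_matrix(pops)
        order = [2, 0, 3, 1]
        m2 = fst_matrix([pops[i] for i in order])
        assert np.allclose(m2.values, m.values[np.ix_(order, order)])


class TestClassicalMds:
    def test_equilateral_three_points(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = classical_mds(d, k=2)
        assert res.variance_fraction == pytest.approx([0.5, 0.5])
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_recovers_known_configuration(self):
        rng = np.random.default_rng(50)
        pts = rng.normal(size=(7, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([f"p{i}" for i in range(7)], D), k=2)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coordinates)
        assert disparity < 1e-8

    def test_rank_one_configuration(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        res = classical_mds(DistanceMatrix(list("abcd"), D), k=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert res.variance_fraction[1] == pytest.approx(0.0, abs=1e-9)

    def test_fractions_non_increasing(self):
        rng = np.random.default_rng(51)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([str(i) for i in range(8)], D), k=3)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_coordinates_centred(self):
        rng = np.random.default_rng(52)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([str(i) for i in range(6)], D), k=2)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)

    def test_cross_check_against_skbio_pcoa(self):
        """Independent oracle: principal coordinates from scikit-bio."""
        rng = np.random.default_rng(53)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([str(i) for i in range(6)], D), k=2)

        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.ordination import pcoa

        ord_ = pcoa(SkbioDM(D), number_of_dimensions=2)
        ref = ord_.samples.values[:, :2]
        for j in range(2):
            col, refcol = res.coordinates[:, j], ref[:, j]
            assert np.allclose(col, refcol, atol=1e-8) or np.allclose(
                col, -refcol, atol=1e-8
            )
        assert np.allclose(
            res.variance_fraction,
            ord_.proportion_explained.values[:2],
            atol=1e-8,
        )

    def test_all_zero_matrix_warns_and_returns_zeros(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            res = classical_mds(d, k=2)
        assert np.allclose(res.coordinates, 0)
        assert np.allclose(res.variance_fraction, 0)

    def test_k_bounds(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            classical_mds(d, k=3)


class TestDistanceMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.25], [0.25, 0]]))
        p = tmp_path / "m.tsv"
        m.to_tsv(str(p))
        m2 = DistanceMatrix.from_tsv(str(p))
        assert m2.labels == ["a", "b"]
        assert np.allclose(m2.values, m.values)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
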