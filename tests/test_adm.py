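import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldseg.adm import (
    AverageDistanceMap,
    RegionAssignment,
    adm_similarity,
    build_adm,
    extract_regions,
    nj_tree,
    pairwise_identity,
    region_density,
    region_eta,
    similarity_identity_curve,
    site_inclusion_profile,
)
from foldseg.distance_stats import range_of_separation
from foldseg.structure_io import Alignment, SequenceRecord
from foldseg.synthetic import make_two_domain_family


def map_from_contacts(contact: np.ndarray) -> AverageDistanceMap:
    """Wrap a hand-made boolean contact matrix (distances are irrelevant)."""
    n = contact.shape[0]
    contact = np.triu(contact, 1) | np.triu(contact, 1).T
    expected = np.where(contact, 5.0, 20.0).astype(float)
    np.fill_diagonal(expected, np.nan)
    return AverageDistanceMap(
        SequenceRecord("toy", "A" * n), expected, 13.0, contact
    )


class TestBuildAdm:
    def test_homopolymer_constant_per_band(self, uniform_stats):
        adm = build_adm("A" * 30, uniform_stats)
        for k in (1, 5, 12, 25):
            band = np.array([adm.expected_distance[i, i + k] for i in range(30 - k)])
            assert np.all(band == band[0])
            assert band[0] == 6.0 + 3.0 * range_of_separation(k)

    def test_symmetric_by_construction(self, uniform_stats):
        adm = build_adm("A" * 25, uniform_stats)
        off = ~np.isnan(adm.expected_distance)
        assert np.array_equal(
            adm.expected_distance[off], adm.expected_distance.T[off]
        )

    def test_two_letter_map_matches_hand_lookup(self, two_letter_stats):
        seq = "AGAAGGAAAGGGAAAAGGGGAGA"
        adm = build_adm(seq, two_letter_stats)
        for i, j in itertools.combinations(range(len(seq)), 2):
            a, b = sorted((seq[i], seq[j]))
            base = {("A", "A"): 5.0, ("A", "G"): 9.0, ("G", "G"): 14.0}[(a, b)]
            expected = base + range_of_separation(j - i)
            assert adm.expected_distance[i, j] == pytest.approx(expected)
            assert adm.predicted_contact[i, j] == (expected <= 13.0)

    def test_short_sequence_rejected(self, uniform_stats):
        with pytest.raises(ValueError, match="too short"):
            build_adm("A" * 19, uniform_stats)

    def test_mostly_unknown_rejected(self, uniform_stats):
        with pytest.raises(ValueError, match="unknown"):
            build_adm("X" * 15 + "A" * 10, uniform_stats)


class TestRegionDensity:
    def test_whole_sequence_eta_zero(self, uniform_stats):
        adm = build_adm("A" * 40, uniform_stats)
        assert region_eta(adm, 1, 40) == 0.0

    def test_all_contacts_inside_region(self):
        contact = np.zeros((30, 30), dtype=bool)
        contact[5:15, 5:15] = True  # dense block at positions 6..15
        adm = map_from_contacts(contact)
        eta = region_eta(adm, 6, 15)
        assert region_density(adm, 6, 15) == 1.0
        assert eta == pytest.approx(1.0 - region_density(adm, 1, 30))
        assert eta > 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        contact = rng.random((30, 30)) < 0.3
        adm = map_from_contacts(contact)
        sym = adm.predicted_contact
        for a, b in [(1, 30), (2, 11), (5, 20), (17, 30), (1, 12)]:
            pairs = list(itertools.combinations(range(a - 1, b), 2))
            brute = sum(sym[i, j] for i, j in pairs) / len(pairs)
            assert region_density(adm, a, b) == pytest.approx(brute)

    def test_exhaustive_all_intervals_length_40(self):
        rng = np.random.default_rng(7)
        contact = rng.random((40, 40)) < 0.4
        adm = map_from_contacts(contact)
        sym = adm.predicted_contact
        for a in range(1, 40):
            for b in range(a + 1, 41):
                pairs = list(itertools.combinations(range(a - 1, b), 2))
                brute = sum(sym[i, j] for i, j in pairs) / len(pairs)
                assert region_density(adm, a, b) == pytest.approx(brute)

    def test_invalid_interval(self, uniform_stats):
        adm = build_adm("A" * 25, uniform_stats)
        with pytest.raises(ValueError):
            region_density(adm, 10, 10)
        with pytest.raises(ValueError):
            region_density(adm, 0, 5)


class TestExtractRegions:
    def test_recovers_planted_two_blocks(self):
        _, stats, truth = make_two_domain_family(80, 40, 5, seed=0)
        adm = build_adm(truth.probe_sequence, stats)
        regions = sorted(extract_regions(adm), key=lambda r: r.start)
        assert len(regions) == 2
        (lo_a, hi_a), (lo_b, hi_b) = truth.blocks
        assert abs(regions[0].start - lo_a) <= 5 and abs(regions[0].end - hi_a) <= 5
        assert abs(regions[1].start - lo_b) <= 5 and abs(regions[1].end - hi_b) <= 5
        assert {r.rank for r in regions} == {"primary", "auxiliary"}
        assert regions[0].dominance == "N" and regions[1].dominance == "C"

    def test_uniform_map_yields_nothing(self):
        contact = np.ones((50, 50), dtype=bool)
        adm = map_from_contacts(contact)
        assert extract_regions(adm) == []

    def test_no_whole_sequence_region(self):
        rng = np.random.default_rng(3)
        contact = rng.random((60, 60)) < 0.5
        adm = map_from_contacts(contact)
        for region in extract_regions(adm):
            assert (region.start, region.end) != (1, 60)

    def test_reported_regions_exceed_threshold_and_do_not_overlap(self):
        _, stats, truth = make_two_domain_family(60, 30, 4, seed=2)
        adm = build_adm(truth.probe_sequence, stats)
        regions = extract_regions(adm, eta_threshold=0.03)
        n = adm.n_residues
        small = [r for r in regions if (r.end - r.start + 1) / n < 0.7]
        for r in regions:
            assert r.eta > 0.03
        for r1, r2 in itertools.combinations(small, 2):
            assert not r1.overlaps(r2)

    def test_source_numbering_offset(self, uniform_stats):
        _, stats, truth = make_two_domain_family(60, 30, 4, seed=3)
        record = SequenceRecord("q", truth.probe_sequence, numbering_offset=100)
        regions = extract_regions(build_adm(record, stats))
        for r in regions:
            assert r.start_source == r.start + 100
            assert r.end_source == r.end + 100


def assignment(length, region, gaps=()):
    gap = np.zeros(length, dtype=bool)
    gap[[g - 1 for g in gaps]] = True
    in_region = np.zeros(length, dtype=bool)
    if region is not None:
        in_region[region[0] - 1 : region[1]] = True
    return RegionAssignment("x", gap, in_region)


class TestAdmSimilarity:
    def test_worked_example(self):
        # 25 sites; A gapped at 3 and 17 with region 6-15; B ungapped, region 8-15
        a = assignment(25, (6, 15), gaps=(3, 17))
        b = assignment(25, (8, 15))
        assert round(adm_similarity(a, b), 1) == 91.3
        assert adm_similarity(a, b) == pytest.approx(100.0 * 21 / 23)

    def test_identical_is_100(self):
        a = assignment(20, (4, 12), gaps=(2,))
        assert adm_similarity(a, a) == 100.0

    def test_complementary_is_0(self):
        a = assignment(10, (1, 5))
        b = assignment(10, (6, 10))
        assert adm_similarity(a, b) == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = RegionAssignment("a", rng.random(30) < 0.1, rng.random(30) < 0.5)
            b = RegionAssignment("b", rng.random(30) < 0.1, rng.random(30) < 0.5)
            s = adm_similarity(a, b)
            assert s == adm_similarity(b, a)
            assert 0.0 <= s <= 100.0
            full_agree = np.all(
                (a.in_region == b.in_region)[~a.gap & ~b.gap]
            )
            assert (s == 100.0) == bool(full_agree)

    def test_no_mutual_sites_raises(self):
        a = assignment(4, None, gaps=(1, 2))
        b = assignment(4, None, gaps=(3, 4))
        with pytest.raises(ValueError, match="no mutually non-gapped"):
            adm_similarity(a, b)

    def test_from_regions_maps_residue_coordinates(self):
        # aligned sequence with gaps: region in residue coords must skip gaps
        aligned = "AC-DE-FG"
        assign = RegionAssignment.from_regions("r", aligned, [(3, 5)])
        # residues: A1 C2 D3 E4 F5 G6 -> region D,E,F at sites 4,5,7 (1-based)
        expected = np.zeros(8, dtype=bool)
        expected[[3, 4, 6]] = True
        assert np.array_equal(assign.in_region, expected)


class TestSiteInclusion:
    def test_identical_assignments_flat_one(self):
        aln = Alignment([("a", "A" * 20), ("b", "A" * 20), ("c", "A" * 20)])
        assigns = [assignment(20, (5, 10)) for _ in range(3)]
        profile = site_inclusion_profile(aln, assigns)
        assert np.all(profile[4:10] == 1.0)
        assert np.all(profile[:4] == 0.0)

    def test_hand_counted_three_records(self):
        aln = Alignment([("a", "AAAAA"), ("b", "AA-AA"), ("c", "AAAAA")])
        assigns = [
            assignment(5, (1, 3)),
            assignment(5, (2, 4), gaps=(3,)),
            assignment(5, (3, 5)),
        ]
        profile = site_inclusion_profile(aln, assigns)
        # site1: a only -> 1/3; site2: a,b -> 2/3; site3: a,c of 2 present -> 2/2
        np.testing.assert_allclose(profile, [1 / 3, 2 / 3, 1.0, 2 / 3, 1 / 3])


class TestSimilarityIdentityCurve:
    def test_all_identical_flat_100(self):
        aln = Alignment([("ref", "ALVKE" * 5)] + [(f"h{i}", "ALVKE" * 5) for i in range(3)])
        assigns = [assignment(25, (5, 12)) for _ in range(4)]
        for a, ident in zip(assigns, aln.identifiers):
            a.identifier = ident
        curve = similarity_identity_curve(aln, assigns, "ref")
        assert curve == [(float(l), 100.0) for l in range(30, 101, 5)]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ALVKEDSTFY"))
        rows = [("ref", "".join(rng.choice(letters, 30)))]
        for i in range(5):
            seq = list(rows[0][1])
            for pos in rng.choice(30, size=rng.integers(2, 12), replace=False):
                seq[pos] = str(rng.choice(letters))
            rows.append((f"h{i}", "".join(seq)))
        aln = Alignment(rows)
        assigns = []
        for ident, _ in rows:
            start = int(rng.integers(1, 10))
            a = assignment(30, (start, start + 10))
            a.identifier = ident
            assigns.append(a)
        curve = dict(similarity_identity_curve(aln, assigns, "ref"))
        ref = assigns[0]
        for limit in range(30, 101, 5):
            sims = [
                adm_similarity(ref, a)
                for (ident, _), a in zip(rows[1:], assigns[1:])
                if pairwise_identity(aln, "ref", ident) >= limit
            ]
            if sims:
                assert curve[float(limit)] == pytest.approx(np.mean(sims))
            else:
                assert float(limit) not in curve


class TestNjTree:
    def test_three_equidistant_star(self):
        sim = np.full((3, 3), 80.0)
        np.fill_diagonal(sim, 100.0)
        newick = nj_tree(sim, ["a", "b", "c"])
        from skbio import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([0.1, 0.1, 0.1])

    def test_recovers_four_taxon_additive_topology(self):
        # planted tree: ((a:1,b:2):3,(c:1.5,d:2.5)) in distance units of 0.01
        branch = {"a": 1.0, "b": 2.0, "c": 1.5, "d": 2.5}
        internal = 3.0
        dist = np.zeros((4, 4))
        ids = ["a", "b", "c", "d"]
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                d = branch[x] + branch[y]
                if {x, y} not in ({"a", "b"}, {"c", "d"}):
                    d += internal
                dist[i, j] = d
        sim = 100.0 * (1.0 - dist / 100.0)  # distances scaled into [0, 1]
        newick = nj_tree(sim, ids)
        from skbio import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        splits = [
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=False)
        ]
        assert any(s in (frozenset("ab"), frozenset("cd")) for s in splits)

    def test_duplicate_rows_zero_branch(self):
        sim = np.array(
            [
                [100.0, 100.0, 60.0, 55.0],
                [100.0, 100.0, 60.0, 55.0],
                [60.0, 60.0, 100.0, 70.0],
                [55.0, 55.0, 70.0, 100.0],
            ]
        )
        newick = nj_tree(sim, ["a", "b", "c", "d"])
        from skbio import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        by_name = {t.name: t.length for t in tree.tips()}
        assert by_name["a"] == pytest.approx(0.0, abs=1e-9)
        assert by_name["b"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(np.eye(2) * 100, ["a", "b"])
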