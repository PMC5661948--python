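import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssearch.io_formats import AlignedFamily, HspRecord
from pssearch.pss_core import (
    DELETION, INSERTION, GapInterval, KnownSite, PermissiveStretch,
    detect_stretches, filter_hits, gap_set, map_known_sites,
    merge_connected, scan_alignment,
)


def hsp(qseq, sseq, qstart=1, evalue=1e-10, identity=0.5, subject="s"):
    qend = qstart + len(qseq) - qseq.count("-") - 1
    return HspRecord("q", subject, qstart, qend, qseq, sseq, evalue, identity)


class TestGapSet:
    def test_insertion_between_flanking_residues(self):
        (g,) = gap_set(hsp("AC-DF", "ACXDF"))
        assert (g.s, g.e, g.kind) == (2, 3, INSERTION)

    def test_deletion_spans_gap_plus_flanks_with_offset(self):
        (g,) = gap_set(hsp("ACDEF", "AC--F", qstart=10))
        assert (g.s, g.e, g.kind) == (11, 14, DELETION)

    def test_gapless_hsp_yields_nothing(self):
        assert gap_set(hsp("ACDEF", "ACDEF")) == []

    def test_interior_deletion_flanks_stay_inside_hsp(self):
        (g,) = gap_set(hsp("ACDEF", "A---F", qstart=1))
        assert (g.s, g.e) == (1, 5)

    def test_terminal_gap_violates_local_alignment_contract(self):
        from pssearch.io_formats import FormatError
        with pytest.raises(FormatError, match="gap"):
            hsp("ACDEF", "-CDEF")

    def test_multiple_indels_sorted(self):
        gs = gap_set(hsp("AC-DEFG", "ACXD--G"))
        assert [(g.s, g.e, g.kind) for g in gs] == [
            (2, 3, INSERTION), (3, 6, DELETION)]

    def test_deletion_interval_always_gap_length_plus_two(self):
        for n in (1, 2, 3):
            (g,) = gap_set(hsp("A" + "CDEFG"[:n + 2], "A" + "-" * n + "XX"[: 2]))
            assert g.e - g.s == n + 1


class TestScanAlignment:
    def test_query_gap_is_insertion(self):
        fam = AlignedFamily("q", {"q": "AC-DF", "h": "ACXDF"})
        (g,) = scan_alignment(fam)
        assert (g.s, g.e, g.kind) == (2, 3, INSERTION)

    def test_homolog_gap_is_deletion_with_flanks(self):
        fam = AlignedFamily("q", {"q": "ACDEFG", "h": "AC--FG"})
        (g,) = scan_alignment(fam)
        assert (g.s, g.e, g.kind) == (2, 5, DELETION)

    def test_terminal_gap_treated_as_missing_data(self):
        fam = AlignedFamily("q", {"q": "ABCDEF".replace("B", "N"),
                                  "h": "---DEF"})
        assert scan_alignment(fam) == []

    def test_min_support_filters_singleton_gaps(self):
        fam = AlignedFamily("q", {"q": "ACDEFG", "h1": "AC--FG", "h2": "ACDEFG"})
        assert len(scan_alignment(fam, min_support=1)) == 1
        assert scan_alignment(fam, min_support=2) == []

    def test_support_counts_rows_gapped_over_run(self):
        fam = AlignedFamily("q", {"q": "ACDEFG", "h1": "AC--FG", "h2": "AC--FG"})
        (g,) = scan_alignment(fam, min_support=2)
        assert g.support == 2


def brute_force_components(intervals):
    """Oracle: union-find over residue sets — intervals join a component iff
    their residue sets intersect (adjacency alone does not join them)."""
    sets = [set(range(g.s, g.e + 1)) for g in intervals]
    parent = list(range(len(sets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                parent[find(i)] = find(j)
    comps = {}
    for i, g in enumerate(intervals):
        comps.setdefault(find(i), []).append(g)
    return sorted((min(g.s for g in c), max(g.e for g in c))
                  for c in comps.values())


class TestMergeConnected:
    def test_shared_residue_merges(self):
        gs = [GapInterval("p", 2, 4, DELETION), GapInterval("p", 4, 7, DELETION)]
        (st,) = merge_connected(gs)
        assert (st.s, st.e, st.label) == (2, 7, "I")
        assert len(st.members) == 2

    def test_adjacent_but_disjoint_do_not_merge(self):
        gs = [GapInterval("p", 2, 3, INSERTION), GapInterval("p", 5, 6, INSERTION)]
        sts = merge_connected(gs)
        assert [(s.s, s.e) for s in sts] == [(2, 3), (5, 6)]
        assert [s.label for s in sts] == ["I", "II"]

    def test_empty_input(self):
        assert merge_connected([]) == []

    def test_mixed_proteins_rejected(self):
        gs = [GapInterval("a", 2, 3, INSERTION), GapInterval("b", 2, 3, INSERTION)]
        with pytest.raises(ValueError, match="multiple proteins"):
            merge_connected(gs)

    def test_matches_brute_force_on_random_interval_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 12)
            gs = []
            for _ in range(n):
                s = int(rng.integers(1, 60))
                e = s + int(rng.integers(1, 8))
                gs.append(GapInterval("p", s, e, DELETION))
            got = [(st.s, st.e) for st in merge_connected(gs)]
            assert got == brute_force_components(gs)

    @given(st.lists(st.tuples(st.integers(1, 40), st.integers(1, 6)),
                    min_size=1, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_order_independent(self, pairs):
        gs = [GapInterval("p", s, s + d, DELETION) for s, d in pairs]
        once = [(st.s, st.e) for st in merge_connected(gs)]
        rev = [(st.s, st.e) for st in merge_connected(list(reversed(gs)))]
        again = [(st.s, st.e) for st in merge_connected(
            [GapInterval("p", s, e, DELETION) for s, e in once])]
        assert once == rev == again


class TestFilterHits:
    def test_good_hit_retained(self):
        h = hsp("A" * 40 + "-" + "A" * 50, "A" * 91, identity=0.45)
        assert "s" in filter_hits({"s": [h]}, query_len=100)

    def test_low_coverage_discarded(self):
        h = hsp("A" * 30 + "-" + "A" * 40, "A" * 71, identity=0.45)
        assert filter_hits({"s": [h]}, query_len=100) == {}

    def test_gapless_hit_discarded(self):
        h = hsp("A" * 95, "A" * 95, identity=0.45)
        assert filter_hits({"s": [h]}, query_len=100) == {}

    def test_high_evalue_hsps_dropped(self):
        h = hsp("A" * 40 + "-" + "A" * 50, "A" * 91, evalue=0.01)
        assert filter_hits({"s": [h]}, query_len=100) == {}

    def test_low_aggregate_identity_discarded(self):
        h = hsp("A" * 40 + "-" + "A" * 50, "A" * 91, identity=0.2)
        assert filter_hits({"s": [h]}, query_len=100) == {}

    def test_coverage_union_across_hsps(self):
        h1 = hsp("A" * 20 + "-" + "A" * 30, "A" * 51, qstart=1, identity=0.5)
        h2 = hsp("A" * 40, "A" * 40, qstart=55, identity=0.5)
        assert "s" in filter_hits({"s": [h1, h2]}, query_len=100)


class TestDetectStretches:
    def test_composition_on_small_fixture(self):
        # two passing hits with overlapping indel evidence at residues 20/21,
        # one hit failing the coverage filter
        good1 = hsp("A" * 19 + "-" + "A" * 80, "A" * 100, subject="s1", identity=0.5)
        good2 = hsp("A" * 20 + "-" + "A" * 79, "A" * 100, subject="s2", identity=0.5)
        low_cov = hsp("A" * 30 + "-" + "A" * 30, "A" * 61, subject="s3", identity=0.5)
        sts = detect_stretches([good1, good2, low_cov], query_len=99)
        assert [(s.s, s.e) for s in sts] == [(19, 21)]

    def test_no_retained_hits_gives_empty(self):
        h = hsp("A" * 50, "A" * 50, identity=0.5)  # gapless
        assert detect_stretches([h], query_len=60) == []

    def test_mixed_queries_rejected(self):
        h1 = hsp("AC-D", "ACXD")
        h2 = HspRecord("other", "s", 1, 3, "ACD", "ACD", 1e-9, 0.5)
        with pytest.raises(ValueError):
            detect_stretches([h1, h2], query_len=10)


class TestMapKnownSites:
    STRETCH = PermissiveStretch("p", 72, 78, label="I")

    @pytest.mark.parametrize("pos,category,dist", [
        (75, "direct", 0), (72, "direct", 0), (78, "direct", 0),
        (70, "scattered", 2), (83, "scattered", 5), (60, "unmapped", 12),
    ])
    def test_categories(self, pos, category, dist):
        (m,) = map_known_sites([KnownSite("p", pos)], [self.STRETCH], window=5)
        assert (m.category, m.distance) == (category, dist)

    def test_categories_partition_and_reorder_invariant(self):
        sites = [KnownSite("p", i) for i in range(60, 90)]
        stretches = [PermissiveStretch("p", 72, 78, label="I"),
                     PermissiveStretch("p", 85, 88, label="II")]
        a = map_known_sites(sites, stretches)
        b = map_known_sites(sites, list(reversed(stretches)))
        counts_a = {c: sum(m.category == c for m in a) for c in
                    ("direct", "scattered", "unmapped")}
        counts_b = {c: sum(m.category == c for m in b) for c in
                    ("direct", "scattered", "unmapped")}
        assert counts_a == counts_b
        assert sum(counts_a.values()) == len(sites)

    def test_same_ss_element(self):
        labels = ["H"] * 70 + ["C"] * 12 + ["H"] * 18  # coil run 71..82
        (m,) = map_known_sites([KnownSite("p", 80)], [self.STRETCH],
                               ss_labels=labels)
        assert m.category == "scattered" and m.same_ss_element is True
        (m2,) = map_known_sites([KnownSite("p", 90)], [self.STRETCH],
                                ss_labels=labels)
        assert m2.same_ss_element is False

    def test_position_outside_protein_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_known_sites([KnownSite("p", 120)], [self.STRETCH],
                            protein_length=100)
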