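"""NUE hexamer scanning, composite merging, PPSG assignment, FUE scanning."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from term3race.construct_io import to_rna
from term3race.signal_scanner import (
    CLASS_PRIORITY,
    NoOverlapError,
    TTSignalSummary,
    aggregate_stats,
    assign_ppsg,
    builtin_catalog,
    catalog_by_sequence,
    catalog_members,
    chain_merge,
    max_overlap_merge,
    merge_composites,
    scan_fue,
    scan_window,
    ure_u_content,
)
from tests.conftest import EXPECTED_EXTRA_MEMBERS, MONOCOT_UBQ_TTS, TABLE1


class TestCatalog:
    def test_size_and_classes(self):
        catalog = builtin_catalog()
        assert len(catalog) == 16
        by_class = {tag: {e.sequence for e in catalog if e.class_tag == tag}
                    for tag in CLASS_PRIORITY}
        assert by_class["canonical"] == {"AAUAAA"}
        assert by_class["aauaaa_like"] == {"AAUAAG", "AAUGAA", "AAUCAA", "AAUUAA",
                                           "UAUAAA", "AAGAAA"}
        assert len(by_class["nue_enriched"]) == 9

    @pytest.mark.parametrize("seq,rice,at_a,at_b", [
        ("AAUAAA", 1, 1, 1),
        ("AUGAAU", 17, 39, 103),
        ("ACAAGU", 100, 594, 0),
        ("GAAUAA", 2, 32, 149),
    ])
    def test_rankings(self, seq, rice, at_a, at_b):
        entry = catalog_by_sequence()[seq]
        assert (entry.rice_rank, entry.at_rank_a, entry.at_rank_b) == (rice, at_a, at_b)

    def test_augaac_variant_excluded(self):
        # AAUGAC does not occur in rice or Arabidopsis NUEs
        assert "AAUGAC" not in catalog_by_sequence()


def brute_force_scan(sequence, site, lo, hi):
    """Enumerate every 6-mer substring, filter by catalog membership and
    window overlap."""
    rna = to_rna(sequence)
    catalog = {e.sequence for e in builtin_catalog()}
    w_lo, w_hi = max(1, site - hi), site - lo
    hits = []
    for start in range(1, len(rna) - 5 + 1):
        kmer = rna[start - 1: start + 5]
        if kmer in catalog and w_hi >= 1 and start <= w_hi and start + 5 >= w_lo:
            hits.append((start, kmer, site - (start + 5)))
    return hits


class TestScanWindow:
    def _planted(self, motif, site, distance, length=120):
        seq = ["C"] * length
        end = site - distance
        seq[end - len(motif): end] = list(motif.replace("U", "T"))
        return "".join(seq)

    def test_planted_hexamer_found_with_distance(self):
        seq = self._planted("AAUAAA", site=100, distance=20)
        hits = scan_window(seq, 100)
        assert [(h.hexamer.sequence, h.distance_to_site) for h in hits] == \
            [("AAUAAA", 20)]

    def test_all_background_sequence_empty(self):
        assert scan_window("C" * 120, 100) == []

    def test_hexamer_outside_window_excluded(self):
        # 3' base 40 nt upstream: span [site-45, site-40], window starts site-35
        seq = self._planted("AAUAAA", site=100, distance=40)
        assert scan_window(seq, 100) == []

    def test_window_truncated_at_sequence_start(self):
        seq = self._planted("AAUAAA", site=20, distance=12)
        hits = scan_window(seq, 20)
        assert len(hits) == 1

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60)
    def test_matches_brute_force_on_random_sequences(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        site = int(rng.integers(36, 301))
        hits = scan_window(seq, site)
        assert [(h.tt_start, h.hexamer.sequence, h.distance_to_site) for h in hits] \
            == brute_force_scan(seq, site, 10, 35)


class TestMerging:
    @pytest.mark.parametrize("a,b,expected", [
        ("AUGAAU", "AAUAAG", "AUGAAUAAG"),  # the 9-nt composite
        ("GAAUAA", "AAUAAA", "GAAUAAA"),  # the heptamer
        ("AUGAAU", "AUGAAU", "AUGAAUGAAU"),  # direct repeat, overlap 2
    ])
    def test_max_overlap_merge(self, a, b, expected):
        assert max_overlap_merge(a, b) == expected

    def test_no_overlap_signalled(self):
        with pytest.raises(NoOverlapError):
            max_overlap_merge("AAAAAA", "CCCCCC")

    def test_chain_merge_four_hexamers(self):
        merged = chain_merge(["AAUGAA", "AUGAAU", "AAUAAA", "AUAAAU"])
        assert merged == "AAUGAAUAAAU"
        assert len(merged) == 11

    def test_chain_merge_single_element_identity(self):
        assert chain_merge(["AAUAAA"]) == "AAUAAA"

    def test_chain_merge_names_failing_pair(self):
        with pytest.raises(NoOverlapError, match="GGGGGG"):
            chain_merge(["AAUAAA", "GGGGGG"])

    @given(st.lists(st.sampled_from([e.sequence for e in builtin_catalog()]),
                    min_size=2, max_size=4))
    @settings(max_examples=100)
    def test_chain_length_identity(self, motifs):
        """Merged length = sum of lengths - sum of pairwise overlaps."""
        try:
            merged = chain_merge(motifs)
        except NoOverlapError:
            return
        # recompute overlaps pair by pair on the growing prefix
        total, prefix = len(motifs[0]), motifs[0]
        for nxt in motifs[1:]:
            step = max_overlap_merge(prefix, nxt)
            total += len(nxt) - (len(prefix) + len(nxt) - len(step))
            prefix = step
        assert len(merged) == total


class TestComposites:
    def test_overlapping_hits_merge_into_composite(self):
        seq = "C" * 60 + "ATGAATAAG" + "C" * 60  # AUGAAU@61 + AAUAAG@64
        hits = scan_window(seq, 61 + 8 + 15)  # site 15 nt downstream of the 3' end
        composites = merge_composites(hits, seq)
        assert len(composites) == 1
        comp = composites[0]
        assert comp.sequence == "AUGAAUAAG"
        assert comp.contains_AUGAAU
        assert comp.classification == "aauaaa_like"  # AAUAAG outranks nue_enriched
        member_seqs = {h.hexamer.sequence for h in comp.members}
        assert {"AUGAAU", "AAUAAG"} <= member_seqs
        # every member occurs in the composite at its recorded offset
        for hit in comp.members:
            off = hit.tt_start - comp.tt_span[0]
            assert comp.sequence[off: off + 6] == hit.hexamer.sequence

    def test_separated_hits_stay_separate(self):
        seq = ("C" * 40 + "AATAAA" + "C" * 20 + "AATAAA" + "C" * 40)
        site = 110
        hits = scan_window(seq, site, lo=1, hi=70)
        composites = merge_composites(hits, seq)
        assert len(composites) == 2

    def test_single_hit_composite_classification(self):
        seq = "C" * 50 + "TATAAA" + "C" * 30
        hits = scan_window(seq, 56 + 20)
        composites = merge_composites(hits, seq)
        assert len(composites) == 1
        assert composites[0].sequence == "UAUAAA"
        assert composites[0].classification == "aauaaa_like"

    def test_composite_equals_chain_merge_of_members(self):
        seq = "C" * 60 + "AATGAATAAAT" + "C" * 60  # the 11-nt composite
        site = 60 + 11 + 15
        hits = scan_window(seq, site)
        composites = merge_composites(hits, seq)
        assert len(composites) == 1
        # chaining the position-sorted members reproduces the read-off sequence
        members = [h.hexamer.sequence for h in composites[0].members]
        assert chain_merge(members) == composites[0].sequence == "AAUGAAUAAAU"


class TestAssignment:
    def _composites(self, seq, site):
        return merge_composites(scan_window(seq, site), seq)

    def test_canonical_wins_over_enriched(self):
        # GAAUAAA = canonical AAUAAA overlapped with GAAUAA, 32 nt upstream
        seq = "C" * 40 + "GAATAAA" + "C" * 40
        site = 40 + 7 + 25  # composite 3' end 25 nt upstream of the site
        assignment = assign_ppsg(site, self._composites(seq, site))
        assert assignment.composite.classification == "canonical"
        assert assignment.composite.sequence == "GAAUAAA"

    def test_class_priority_beats_proximity(self):
        # an AAUAAA-like motif farther away beats a closer NUE-enriched one
        seq = "C" * 30 + "AATAAG" + "C" * 4 + "GAAGAA" + "C" * 40
        site = 30 + 6 + 4 + 6 + 12
        comps = self._composites(seq, site)
        assert {c.classification for c in comps} == {"aauaaa_like", "nue_enriched"}
        assignment = assign_ppsg(site, comps)
        assert assignment.composite.classification == "aauaaa_like"

    def test_no_composites_gives_none(self):
        assignment = assign_ppsg(100, [])
        assert assignment.composite is None and assignment.distance is None

    def test_deterministic_under_permutation(self):
        seq = "C" * 30 + "AATAAG" + "C" * 4 + "GAAGAA" + "C" * 40
        site = 30 + 6 + 4 + 6 + 12
        comps = self._composites(seq, site)
        chosen = {assign_ppsg(site, list(perm)).composite.sequence
                  for perm in itertools.permutations(comps)}
        assert len(chosen) == 1


class TestFueAndUre:
    def test_gc_rich_motif_downstream(self):
        seq = "A" * 120 + "CGTGTCTT" + "A" * 30
        site = 109  # motif starts 12 nt downstream of the site
        hits = scan_fue(seq, site)
        gc = [h for h in hits if h.motif_kind == "gc_rich_stability"]
        assert [(h.sequence, h.relative_to_site) for h in gc] == [("CGUGUCUU", 12)]

    @pytest.mark.parametrize("motif", ["CGTGTCTG", "CGTGTCTA", "CGTGTCAT", "CGTGTCAG"])
    def test_gc_rich_pattern_tolerates_last_two_bases(self, motif):
        seq = "A" * 50 + motif + "A" * 50
        hits = scan_fue(seq, 80)
        assert any(h.motif_kind == "gc_rich_stability" for h in hits)

    def test_u_rich_repeat_with_one_mismatch(self):
        seq = "C" * 60 + "TTTGTG" + "C" * 60  # one mismatch from UUUGUA
        hits = scan_fue(seq, 100)
        u = [h for h in hits if h.motif_kind == "u_rich_repeat"]
        assert [(h.tt_start, h.relative_to_site) for h in u] == [(61, -39)]

    def test_all_a_sequence_no_hits(self):
        assert scan_fue("A" * 200, 100) == []

    @pytest.mark.parametrize("up,down,expected", [
        ("T" * 10, "T" * 10, (1.0, 1.0)),
        ("G" * 10, "G" * 10, (0.0, 0.0)),
        ("TTTTTGGGGG", "G" * 10, (0.5, 0.0)),
    ])
    def test_ure_u_content(self, up, down, expected):
        seq = "C" * 40 + up + "A" + down + "C" * 40
        assert ure_u_content(seq, 51) == pytest.approx(expected)

    def test_ure_truncated_at_edges(self):
        up_frac, down_frac = ure_u_content("TTA", 3)
        assert up_frac == 1.0 and down_frac == 0.0


def table1_summaries():
    return [
        TTSignalSummary(tt_id=tt, unique_site_count=n,
                        ppsg_sequences=tuple(p for p, _ in ppsgs))
        for tt, n, ppsgs in TABLE1
    ]


class TestAggregateStats:
    def test_augaau_motif_in_six_of_eight_tts(self):
        stats = aggregate_stats(table1_summaries())
        assert stats["n_tts"] == 8
        assert stats["n_tts_with_query_motif"] == 6
        assert set(stats["tts_with_query_motif"]) == \
            {"SiUbi2", "BdUbi1", "BdUbi1-C", "ZmUbi1", "AtELF1", "AtUbi10"}

    def test_ppsg_coverage_72_percent(self):
        stats = aggregate_stats(table1_summaries())
        assert stats["n_unique_sites"] == 18
        assert stats["n_assigned_sites"] == 13
        assert stats["ppsg_coverage_percent"] == 72

    def test_site_count_range(self):
        stats = aggregate_stats(table1_summaries())
        assert (stats["site_count_min"], stats["site_count_max"]) == (1, 3)

    def test_exact_composite_in_three_monocot_ubq_tts(self):
        stats = aggregate_stats(table1_summaries(), exact_query="AUGAAUAAG",
                                subset=MONOCOT_UBQ_TTS)
        assert stats["n_tts_with_exact_ppsg"] == 3

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_stats([])


class TestTable1Recovery:
    @pytest.mark.parametrize("ppsg,listed", [
        (p, members) for _, _, ppsgs in TABLE1 for p, members in ppsgs
    ])
    def test_printed_ppsg_strings_recover_listed_hexamers(self, ppsg, listed):
        found = {entry.sequence for entry, _ in catalog_members(ppsg)}
        assert listed <= found
        assert found == listed | EXPECTED_EXTRA_MEMBERS.get(ppsg, set())

    def test_direct_repeat_yields_two_positioned_hits(self):
        # the 10-nt AUGAAU direct repeat carries two copies of the hexamer
        hits = [(e.sequence, pos) for e, pos in catalog_members("AUGAAUGAAU")
                if e.sequence == "AUGAAU"]
        assert hits == [("AUGAAU", 1), ("AUGAAU", 5)]
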