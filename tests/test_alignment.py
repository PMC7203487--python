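"""Chain compositing, difference columns, unique layout and statistics."""

import numpy as np
import pytest

from dnacanvas.alignment import (
    PROVENANCE_COLORS,
    CompositeAlignment,
    chain_coverage_profile,
    composite_alignment,
    compute_stats,
    difference_columns,
    render_four_column,
    sort_and_select_chains,
    stats_table,
    unique_sequence,
)
from dnacanvas.io_formats import Chain, ChainBlock, Contig, revcomp
from conftest import random_contig


def simple_chain(score, tName, tLen, tStart, tEnd, qName, qLen, qStart, qEnd,
                 blocks, qStrand="+", chain_id=1):
    c = Chain(score, tName, tLen, "+", tStart, tEnd, qName, qLen, qStrand,
              qStart, qEnd, chain_id, [ChainBlock(*b) for b in blocks])
    c.validate()
    return c


@pytest.fixture
def toy():
    """The 30 bp reference with a dt=2 gap against a 28 bp query."""
    ref = random_contig(30, 1, "chrR")
    query = Contig("chrQ", ref.seq[:10] + ref.seq[12:])
    chain = simple_chain(4900, "chrR", 30, 0, 30, "chrQ", 28, 0, 28,
                         [(10, 2, 0), (18,)])
    return ref, query, chain


class TestChainSelection:
    def test_master_is_highest_score(self, toy):
        ref, query, chain = toy
        low = simple_chain(100, "chrR", 30, 20, 25, "chrQ", 28, 20, 25, [(5,)], chain_id=2)
        master, others = sort_and_select_chains([low, chain], "chrR")
        assert master.score == 4900
        assert others == [low]

    def test_others_sorted_by_tstart(self):
        chains = [
            simple_chain(10, "chrR", 100, 50, 60, "q", 100, 0, 10, [(10,)], chain_id=2),
            simple_chain(999, "chrR", 100, 0, 10, "q", 100, 20, 30, [(10,)], chain_id=1),
            simple_chain(20, "chrR", 100, 30, 40, "q", 100, 40, 50, [(10,)], chain_id=3),
        ]
        master, others = sort_and_select_chains(chains, "chrR")
        assert master.chain_id == 1
        assert [c.tStart for c in others] == [30, 50]

    def test_no_chain_for_reference(self):
        master, others = sort_and_select_chains([], "chrZ")
        assert master is None and others == []


class TestComposite:
    def test_toy_dt_gap(self, toy):
        ref, query, chain = toy
        comp = composite_alignment(ref, [query], [chain])
        assert comp.ref_gapped == ref.seq  # no gaps inserted in reference
        assert comp.query_gapped[10:12] == "--"
        assert comp.query_gapped.replace("-", "") == query.seq
        assert compute_stats(comp).alignment_length == 28

    def test_dq_gap_conserves_reference(self):
        ref = random_contig(30, 2, "chrR")
        extra = "GGGGG"
        query = Contig("chrQ", ref.seq[:10] + extra + ref.seq[10:])
        chain = simple_chain(900, "chrR", 30, 0, 30, "chrQ", 35, 0, 35,
                             [(10, 0, 5), (20,)])
        comp = composite_alignment(ref, [query], [chain])
        assert "-" * 5 in comp.ref_gapped
        assert comp.ref_gapped.replace("-", "") == ref.seq
        assert comp.query_gapped.replace("-", "") == query.seq

    def test_secondary_chain_classes(self):
        ref = random_contig(60, 3, "chrR")
        # master covers [0,20); same-name secondary covers [30,40);
        # different-name secondary covers [50,60)
        q_main = Contig("chrQ", ref.seq[0:20] + ref.seq[30:40])
        q_other = Contig("chrZ", ref.seq[50:60])
        chains = [
            simple_chain(1000, "chrR", 60, 0, 20, "chrQ", 30, 0, 20, [(20,)], chain_id=1),
            simple_chain(50, "chrR", 60, 30, 40, "chrQ", 30, 20, 30, [(10,)], chain_id=2),
            simple_chain(40, "chrR", 60, 50, 60, "chrZ", 10, 0, 10, [(10,)], chain_id=3),
        ]
        comp = composite_alignment(ref, [q_main, q_other], chains)
        cls_at = {}
        for iv in comp.provenance:
            for p in range(iv.start, iv.end):
                cls_at[p] = iv.cls
        assert cls_at[5] == "syntenic"
        assert cls_at[25] == "unaligned_ref"
        assert cls_at[35] == "intra"
        assert cls_at[55] == "inter"

    def test_minus_strand_chain_reverse_complements(self):
        ref = random_contig(40, 4, "chrR")
        # query carries the reverse complement of ref[10:30] at its start
        seg = ref.seq[10:30]
        query = Contig("chrQ", revcomp(seg) + "ACGTACGT")
        q_size = query.length
        # on '-' strand coordinates, the segment occupies [q_size-20, q_size)
        chain = simple_chain(500, "chrR", 40, 10, 30, "chrQ", q_size,
                             q_size - 20, q_size, [(20,)], qStrand="-")
        comp = composite_alignment(ref, [query], [chain])
        assert comp.query_gapped[10:30] == seg  # back on the forward strand

    def test_overlap_truncated(self, caplog):
        ref = random_contig(30, 5, "chrR")
        q = Contig("chrQ", ref.seq)
        chains = [
            simple_chain(1000, "chrR", 30, 0, 20, "chrQ", 30, 0, 20, [(20,)], chain_id=1),
            simple_chain(10, "chrR", 30, 15, 25, "chrQ", 30, 15, 25, [(10,)], chain_id=2),
        ]
        comp = composite_alignment(ref, [q], chains)
        # positions 15-19 stay with the master; 20-24 filled by the secondary
        for iv in comp.provenance:
            if iv.start <= 15 < iv.end:
                assert iv.cls == "syntenic"
            if iv.start <= 22 < iv.end:
                assert iv.cls == "intra"

    def test_provenance_partitions_gapped_length(self, toy):
        ref, query, chain = toy
        comp = composite_alignment(ref, [query], [chain])
        cursor = 0
        for iv in comp.provenance:
            assert iv.start == cursor
            cursor = iv.end
        assert cursor == len(comp.ref_gapped)


class TestDifferenceColumns:
    def test_mismatch_appears_on_both_sides(self):
        comp = CompositeAlignment("r", "ACGT", "ACGA")
        assert difference_columns(comp) == ("---T", "---A")

    def test_identical_is_all_background(self):
        comp = CompositeAlignment("r", "ACGT", "ACGT")
        assert difference_columns(comp) == ("----", "----")

    def test_gap_rule(self):
        comp = CompositeAlignment("r", "AC-T", "ACGT")
        ref_u, query_u = difference_columns(comp)
        assert query_u == "--G-"
        assert ref_u == "----"

    def test_case_insensitive_compare(self):
        comp = CompositeAlignment("r", "acgt", "ACGT")
        assert difference_columns(comp) == ("----", "----")


class TestUnique:
    def test_toy_unique_is_dt_bases(self, toy):
        ref, query, chain = toy
        comp = composite_alignment(ref, [query], [chain])
        u = unique_sequence(comp)
        assert u.seq == ref.seq[10:12]

    def test_full_coverage_empty_unique(self):
        ref = random_contig(20, 6, "chrR")
        q = Contig("chrQ", ref.seq)
        chain = simple_chain(100, "chrR", 20, 0, 20, "chrQ", 20, 0, 20, [(20,)])
        comp = composite_alignment(ref, [q], [chain])
        assert unique_sequence(comp).length == 0


class TestStats:
    def test_ninety_percent_identity(self):
        comp = CompositeAlignment("r", "ACGTACGTAC", "ACGTACGTAT")
        st = compute_stats(comp)
        assert (st.identical, st.non_identical) == (9, 1)
        assert st.identity_pct == pytest.approx(90.0)

    def test_identity_invariant(self, toy):
        ref, query, chain = toy
        st = compute_stats(composite_alignment(ref, [query], [chain]))
        assert st.identical + st.non_identical == st.alignment_length
        assert st.alignment_length + st.unaligned_ref == st.ref_len_with_N

    def test_n_positions_tallied_separately(self):
        comp = CompositeAlignment("r", "ANGT", "AAGT")
        st = compute_stats(comp)
        assert st.refN_to_query_bp == 1
        assert st.identical == 3 and st.non_identical == 0
        assert st.ref_len_no_N == 3

    def test_gap_run_thresholds(self):
        ref_gapped = "A" * 5 + "C" * 12 + "G" * 5  # query misses the middle 12
        query_gapped = "A" * 5 + "-" * 12 + "G" * 5
        st = compute_stats(CompositeAlignment("r", ref_gapped, query_gapped))
        assert (st.ref_gap_count, st.ref_gaps_gt10, st.ref_gaps_gt100) == (1, 1, 0)
        assert st.query_gap_count == 0

    def test_empty_alignment_zero_percentages(self):
        st = compute_stats(CompositeAlignment("r", "ACGT", "----"))
        assert st.coverage_pct == 0.0 and st.identity_pct == 0.0

    def test_stats_table_rows(self, toy):
        ref, query, chain = toy
        st = compute_stats(composite_alignment(ref, [query], [chain]))
        table = stats_table({"chrR": st})
        assert "Number of gaps introduced in reference by alignment\t1" in table
        assert table.startswith("Feature\tchrR")


class TestCoverageProfile:
    def test_single_chain_fifty_percent(self):
        ref = random_contig(30, 7, "chr1")
        chain = simple_chain(100, "chr1", 30, 0, 15, "chr1", 20, 0, 15, [(15,)])
        prof = chain_coverage_profile([chain], [ref])
        assert prof["coverage_pct"][1] == pytest.approx(50.0)

    def test_topk_monotone(self):
        ref = random_contig(100, 8, "chr1")
        chains = [
            simple_chain(90, "chr1", 100, 0, 40, "chr1", 100, 0, 40, [(40,)], chain_id=1),
            simple_chain(50, "chr1", 100, 50, 70, "chr1", 100, 50, 70, [(20,)], chain_id=2),
            simple_chain(10, "chr1", 100, 80, 90, "chr1", 100, 80, 90, [(10,)], chain_id=3),
        ]
        prof = chain_coverage_profile(chains, [ref])
        cov = prof["coverage_pct"]
        assert cov[1] <= cov[2] <= cov[3] <= cov["all"]
        assert cov["all"] == pytest.approx(70.0)

    def test_homolog_split_with_name_map(self):
        ref = random_contig(100, 9, "chr2")
        chains = [
            simple_chain(90, "chr2", 100, 0, 40, "chr2A", 100, 0, 40, [(40,)], chain_id=1),
            simple_chain(50, "chr2", 100, 50, 70, "chr2B", 100, 0, 20, [(20,)], chain_id=2),
            simple_chain(10, "chr2", 100, 80, 90, "chr5", 100, 0, 10, [(10,)], chain_id=3),
        ]
        prof = chain_coverage_profile(chains, [ref], homolog_map={"2A": "2", "2B": "2"})
        assert prof["homolog_pct_excluded"] == pytest.approx(60.0)
        assert prof["non_homolog_pct_excluded"] == pytest.approx(10.0)


class TestFourColumnRender:
    def test_background_colors_by_provenance(self):
        ref = random_contig(60, 10, "chrR")
        q_main = Contig("chrQ", ref.seq[0:20] + ref.seq[30:40])
        q_other = Contig("chrZ", ref.seq[50:60])
        chains = [
            simple_chain(1000, "chrR", 60, 0, 20, "chrQ", 30, 0, 20, [(20,)], chain_id=1),
            simple_chain(50, "chrR", 60, 30, 40, "chrQ", 30, 20, 30, [(10,)], chain_id=2),
            simple_chain(40, "chrR", 60, 50, 60, "chrZ", 10, 0, 10, [(10,)], chain_id=3),
        ]
        comp = composite_alignment(ref, [q_main, q_other], chains)
        from dnacanvas.tile_layout import TileLayout

        layout = TileLayout(radices=(10, 10), paddings=(0, 0))
        img = np.asarray(render_four_column(comp, layout=layout, gutter=2))
        # panel 2 (ref-unique) is mostly background: read colors there
        panel_x0 = 1 * (10 + 2)
        # index 35 -> (x=5, y=3): intra background
        assert tuple(img[3, panel_x0 + 5]) == PROVENANCE_COLORS["intra"]
        # index 55 -> (x=5, y=5): inter background
        assert tuple(img[5, panel_x0 + 5]) == PROVENANCE_COLORS["inter"]
        # index 5 (syntenic) in the same panel: white
        assert tuple(img[0, panel_x0 + 5]) == PROVENANCE_COLORS["syntenic"]
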