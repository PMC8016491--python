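"""Signature extraction from intra- and inter-alignment discordancies."""
import pytest

from asmsv.model import AlignmentSegment, Parameters, reverse_complement
from asmsv.signature_collection import (
    analyze_segment_triples,
    classify_segment_pair,
    collect,
    extract_intra_signatures,
)
from asmsv.synthetic_genome import emit_alignments, generate_reference, implant_svs
from asmsv.alignment_io import segment_from_pysam

from helpers import flip_segment, make_segment


def _segment_with_cigar(cigar, ref_start=1000, strand="+", seq=None):
    from asmsv.alignment_io import query_interval_on_forward_strand

    qs, qe, qlen = query_interval_on_forward_strand(cigar, strand)
    ref_span = sum(l for op, l in cigar if op in ("M", "=", "X", "D"))
    return AlignmentSegment(
        query_name="contig",
        query_start=qs,
        query_end=qe,
        query_length=qlen,
        ref_name="chr1",
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        strand=strand,
        cigar=cigar,
        query_sequence=seq,
        haplotype=1,
    )


class TestIntraAlignment:
    def test_gapless_cigar_yields_nothing(self, params):
        assert extract_intra_signatures(_segment_with_cigar([("M", 100)]), params) == []

    def test_deletion_gap_placed_by_reference_cursor(self, params):
        seg = _segment_with_cigar([("M", 50), ("D", 75), ("M", 50)])
        (sig,) = extract_intra_signatures(seg, params)
        assert (sig.sv_type, sig.start, sig.end, sig.sv_length) == ("DEL", 1050, 1125, 75)

    def test_sub_threshold_gaps_are_ignored(self, params):
        seq = "A" * 160
        seg = _segment_with_cigar(
            [("M", 50), ("I", 60), ("M", 50), ("D", 30), ("M", 10)], seq=seq
        )
        (sig,) = extract_intra_signatures(seg, params)
        assert sig.sv_type == "INS"
        assert sig.start == sig.end == 1050
        assert sig.sv_length == 60
        assert sig.alt_sequence == seq[50:110]

    def test_insertion_without_sequence_gets_empty_alt(self, params):
        seg = _segment_with_cigar([("M", 50), ("I", 60), ("M", 50)], seq=None)
        (sig,) = extract_intra_signatures(seg, params)
        assert sig.alt_sequence == "" and sig.sv_length == 60


class TestSegmentPairs:
    def test_concordant_pair(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2000, 3000, "+", 1000, 2000)
        assert classify_segment_pair(a, b, params) == []

    def test_reference_gap_is_deletion(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2500, 3000, "+", 1005, 1505)
        (sig,) = classify_segment_pair(a, b, params)
        assert (sig.sv_type, sig.start, sig.end, sig.sv_length) == ("DEL", 2000, 2500, 500)

    def test_reference_overlap_is_tandem_duplication(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 1700, 2600, "+", 1010, 1910)
        (sig,) = classify_segment_pair(a, b, params)
        assert (sig.sv_type, sig.start, sig.end, sig.sv_length) == (
            "DUP_TANDEM", 1700, 2000, 300,
        )

    def test_query_gap_is_insertion_with_sequence(self, params):
        full = "ACGT" * 500  # 2000 bp contig
        a = make_segment("chr1", 1000, 2000, "+", 0, 950, full_query_sequence=full)
        b = make_segment("chr1", 2000, 3000, "+", 1050, 2000, full_query_sequence=full)
        (sig,) = classify_segment_pair(a, b, params)
        assert (sig.sv_type, sig.start, sig.sv_length) == ("INS", 2000, 100)
        assert sig.alt_sequence == full[950:1050]

    def test_replacement_yields_deletion_and_insertion(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2400, 3000, "+", 1200, 1800)
        types = sorted(s.sv_type for s in classify_segment_pair(a, b, params))
        assert types == ["DEL", "INS"]

    def test_interchromosomal_jump_is_breakend_pair(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr5", 500, 1400, "+", 1000, 1900)
        sigs = classify_segment_pair(a, b, params)
        assert [s.sv_type for s in sigs] == ["BND", "BND"]
        adj1, adj2 = sigs[0].adjacency, sigs[1].adjacency
        assert adj2 == adj1.reciprocal()
        assert (adj1.chrom1, adj1.pos1, adj1.dir1) == ("chr1", 1999, "right")
        assert (adj1.chrom2, adj1.pos2, adj1.dir2) == ("chr5", 500, "left")

    def test_long_same_chromosome_jump_is_breakend_pair(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 500_000, 501_000, "+", 1000, 2000)
        assert [s.sv_type for s in classify_segment_pair(a, b, params)] == ["BND", "BND"]

    @pytest.mark.parametrize("case", ["del", "dup", "ins"])
    def test_invariant_under_contig_reverse_complement(self, params, case):
        """Flipping the contig (swap + strand-flip a and b) keeps class and locus."""
        full = "ACGT" * 500
        if case == "del":
            a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
            b = make_segment("chr1", 2500, 3000, "+", 1005, 1505)
        elif case == "dup":
            a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
            b = make_segment("chr1", 1700, 2600, "+", 1010, 1910)
        else:
            a = make_segment("chr1", 1000, 2000, "+", 0, 950, full_query_sequence=full)
            b = make_segment("chr1", 2000, 3000, "+", 1050, 2000, full_query_sequence=full)
        qlen = 2000
        fa, fb = flip_segment(b, qlen), flip_segment(a, qlen)
        fa.full_query_sequence = fb.full_query_sequence = (
            reverse_complement(full) if case == "ins" else None
        )
        original = classify_segment_pair(a, b, params)
        flipped = classify_segment_pair(fa, fb, params)
        key = lambda s: (s.sv_type, s.ref_name, s.start, s.end, s.sv_length)
        assert [key(s) for s in original] == [key(s) for s in flipped]
        if case == "ins":
            assert original[0].alt_sequence == flipped[0].alt_sequence


class TestSegmentTriples:
    def _inv_triple(self):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2000, 2500, "-", 1000, 1500)
        c = make_segment("chr1", 2500, 3000, "+", 1500, 2000)
        return [a, b, c]

    def test_inversion_geometry(self, params):
        (sig,) = analyze_segment_triples(self._inv_triple(), params)
        assert (sig.sv_type, sig.start, sig.end, sig.sv_length) == ("INV", 2000, 2500, 500)

    def test_interspersed_duplication_geometry(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr7", 9000, 9600, "+", 1000, 1600)
        c = make_segment("chr1", 2000, 3000, "+", 1600, 2600)
        (sig,) = analyze_segment_triples([a, b, c], params)
        assert sig.sv_type == "DUP_INT"
        assert sig.start == sig.end == 2000
        assert sig.source_interval == ("chr7", 9000, 9600)
        assert sig.sv_length == 600

    def test_collinear_triple_is_concordant(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2000, 2500, "+", 1000, 1500)
        c = make_segment("chr1", 2500, 3000, "+", 1500, 2000)
        assert analyze_segment_triples([a, b, c], params) == []

    def test_consumed_pairs_do_not_leak_breakends(self, params):
        sigs = collect(self._inv_triple(), params)
        assert [s.sv_type for s in sigs] == ["INV"]

    def test_unconsumed_orientation_switch_becomes_breakend_pair(self, params):
        a = make_segment("chr1", 1000, 2000, "+", 0, 1000)
        b = make_segment("chr1", 2000, 2500, "-", 1000, 1500)
        sigs = collect([a, b], params)
        assert [s.sv_type for s in sigs] == ["BND", "BND"]


class TestCollect:
    def test_empty_stream(self, params):
        assert collect([], params) == []

    def test_single_gapped_record(self, params):
        seg = _segment_with_cigar([("M", 200), ("D", 100), ("M", 200)])
        sigs = collect([seg], params)
        assert [s.sv_type for s in sigs] == ["DEL"]

    def test_fixture_contig_with_inversion_and_deletion(self, params):
        reference = generate_reference(1, 30_000, seed=5)
        hap1, hap2, truth = implant_svs(
            reference,
            [("INV", (500, 500), 1, 1.0), ("DEL", (80, 80), 1, 1.0)],
            seed=6,
        )
        header, records = emit_alignments({1: hap1}, truth, reference, style="gapped")
        segments = [segment_from_pysam(r, haplotype=1) for r in records[1]]
        sigs = collect(segments, params)
        assert sorted(s.sv_type for s in sigs) == ["DEL", "INV"]
        by_type = {s.sv_type: s for s in sigs}
        for t in truth:
            sig = by_type[t.sv_type]
            assert (sig.start, sig.end) == (t.start, t.end)
            assert sig.sv_length == t.sv_length
            assert sig.haplotype == 1

    def test_signatures_lie_within_reference_bounds(self, params, benchmark_fixture):
        reference = benchmark_fixture["reference"]
        for hap in (1, 2):
            segments = [
                segment_from_pysam(r, haplotype=hap)
                for r in benchmark_fixture["records"][hap]
            ]
            for sig in collect(segments, params):
                assert 0 <= sig.start <= sig.end <= len(reference[sig.ref_name])
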