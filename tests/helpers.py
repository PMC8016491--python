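"""Shared test utilities: independent oracles and pipeline shortcuts."""
from __future__ import annotations

import numpy as np

from asmsv.alignment_io import read_alignments
from asmsv.model import AlignmentSegment, Parameters, reverse_complement
from asmsv.pairing_genotyping import (
    candidates_from_signatures,
    dedup_within_haplotype,
    pair_and_genotype,
)
from asmsv.signature_collection import collect


def levenshtein_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming Levenshtein oracle (row-wise, numpy).

    The insertion relaxation cur[j] = min(m[j], cur[j-1] + 1) is solved in
    closed form as min_{k<=j} (m[k] + j - k) via a prefix minimum.
    """
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    idx = np.arange(bb.size + 1)
    prev = idx.copy()
    for ch in a.encode():
        m = np.empty(bb.size + 1, dtype=np.int64)
        m[0] = prev[0] + 1
        m[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (bb != ch))
        prev = np.minimum.accumulate(m - idx) + idx
    return int(prev[-1])


def make_segment(
    ref_name,
    ref_start,
    ref_end,
    strand,
    q_start,
    q_end,
    query_name="contig",
    haplotype=1,
    query_length=None,
    full_query_sequence=None,
):
    """Bare alignment segment for geometry tests (CIGAR = single M block)."""
    if query_length is None:
        query_length = q_end
    return AlignmentSegment(
        query_name=query_name,
        query_start=q_start,
        query_end=q_end,
        query_length=query_length,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        cigar=[("M", q_end - q_start)],
        haplotype=haplotype,
        mapq=60,
        full_query_sequence=full_query_sequence,
    )


def flip_segment(seg: AlignmentSegment, query_length: int) -> AlignmentSegment:
    """Coordinates of the same alignment after reverse-complementing the contig."""
    return AlignmentSegment(
        query_name=seg.query_name,
        query_start=query_length - seg.query_end,
        query_end=query_length - seg.query_start,
        query_length=query_length,
        ref_name=seg.ref_name,
        ref_start=seg.ref_start,
        ref_end=seg.ref_end,
        strand="-" if seg.strand == "+" else "+",
        cigar=list(seg.cigar),
        haplotype=seg.haplotype,
        mapq=seg.mapq,
    )


def diploid_calls_from_sams(paths, params: Parameters):
    per_hap = []
    for hap in (1, 2):
        segments = list(read_alignments(paths[hap], haplotype=hap))
        per_hap.append(dedup_within_haplotype(collect(segments, params), params))
    return pair_and_genotype(per_hap[0], per_hap[1], params)


def haploid_calls_from_sam(path, params: Parameters):
    segments = list(read_alignments(path))
    signatures = dedup_within_haplotype(collect(segments, params), params)
    return candidates_from_signatures(signatures, genotype="unknown")


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reconstruct_contig(segments, reference) -> str:
    """CIGAR-apply oracle: rebuild a contig from reference slices + CIGARs.

    Matched bases come from the reference, inserted/soft-clipped bases from
    the record's stored sequence. Positions written by several records
    (e.g. reference-derived match bases vs. a primary record's soft clip)
    must agree, which makes the reconstruction a coordinate-consistency
    check, and the final contig must be fully tiled.
    """
    query_length = segments[0].query_length
    out = [None] * query_length

    for seg in segments:
        ref_seq = reference[seg.ref_name]
        hard_lead = seg.cigar[0][1] if seg.cigar[0][0] == "H" else 0

        def place(aln_pos, base):
            pos = aln_pos if seg.strand == "+" else query_length - 1 - aln_pos
            base = base if seg.strand == "+" else _COMP[base]
            assert out[pos] is None or out[pos] == base, "conflicting placements"
            out[pos] = base

        r = seg.ref_start
        a = 0  # position on the full query, alignment orientation
        stored = seg.query_sequence or ""
        for op, length in seg.cigar:
            if op in ("M", "=", "X"):
                for k in range(length):
                    place(a + k, ref_seq[r + k])
                r += length
                a += length
            elif op == "I":
                for k in range(length):
                    place(a + k, stored[a - hard_lead + k])
                a += length
            elif op == "S":
                for k in range(length):
                    place(a + k, stored[a - hard_lead + k])
                a += length
            elif op == "D":
                r += length
            elif op == "H":
                a += length
    assert all(base is not None for base in out), "contig not fully tiled"
    return "".join(out)
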