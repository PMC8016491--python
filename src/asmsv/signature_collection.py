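"""COLLECT step: extract SV signatures from discordant contig alignments.

Two sources of evidence are analyzed per haplotype:

* intra-alignment discordancies — long insertion/deletion gaps inside a
  single alignment record's CIGAR;
* inter-alignment discordancies — position and orientation conflicts
  between the split-alignment segments of one contig (deletions, insertions,
  tandem duplications from overlapping placements, inversions and
  interspersed duplications from three-segment geometries, and translocation
  breakends for everything that jumps too far).
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .model import (
    AlignmentSegment,
    BreakendAdjacency,
    Parameters,
    SvSignature,
    reverse_complement,
)

__all__ = [
    "extract_intra_signatures",
    "classify_segment_pair",
    "analyze_segment_triples",
    "collect",
]


def _forward_query_bases(seg: AlignmentSegment, qstart: int, qend: int) -> str:
    """Bases of the forward-oriented contig over [qstart, qend), if recoverable.

    Falls back to the record's own (possibly hard-clipped) stored sequence
    when no full-length sequence was attached; returns "" when the interval
    is not covered.
    """
    if qstart >= qend:
        return ""
    if seg.full_query_sequence is not None and len(seg.full_query_sequence) >= qend:
        return seg.full_query_sequence[qstart:qend]
    seq = seg.query_sequence
    if not seq:
        return ""
    hard_lead = seg.cigar[0][1] if seg.cigar and seg.cigar[0][0] == "H" else 0
    hard_trail = seg.cigar[-1][1] if seg.cigar and seg.cigar[-1][0] == "H" else 0
    lo, hi = hard_lead, seg.query_length - hard_trail  # stored span, aln orientation
    if seg.strand == "+":
        if qstart < lo or qend > hi:
            return ""
        return seq[qstart - lo : qend - lo]
    a_start, a_end = seg.query_length - qend, seg.query_length - qstart
    if a_start < lo or a_end > hi:
        return ""
    return reverse_complement(seq[a_start - lo : a_end - lo])


def extract_intra_signatures(segment: AlignmentSegment, params: Parameters) -> List[SvSignature]:
    """Extract DEL/INS signatures from long CIGAR gaps of one record.

    Deletions are placed at the reference span of the D operation; insertions
    are anchored at the reference position where the alignment is
    interrupted, with the inserted contig bases as alt sequence (SAM stores
    the sequence in reference orientation already).
    """
    out: List[SvSignature] = []
    ref_cursor = segment.ref_start
    seq_cursor = 0  # position in the stored (alignment-oriented) sequence
    seq = segment.query_sequence
    for op, length in segment.cigar:
        if op in ("M", "=", "X"):
            ref_cursor += length
            seq_cursor += length
        elif op == "S":
            seq_cursor += length
        elif op == "I":
            if length >= params.min_sv_size:
                alt = seq[seq_cursor : seq_cursor + length] if seq else ""
                out.append(
                    SvSignature(
                        sv_type="INS",
                        ref_name=segment.ref_name,
                        start=ref_cursor,
                        end=ref_cursor,
                        sv_length=length,
                        alt_sequence=alt,
                        haplotype=segment.haplotype,
                        origin="intra",
                        query_name=segment.query_name,
                        evidence_span=segment.query_span,
                    )
                )
            seq_cursor += length
        elif op == "D":
            if length >= params.min_sv_size:
                out.append(
                    SvSignature(
                        sv_type="DEL",
                        ref_name=segment.ref_name,
                        start=ref_cursor,
                        end=ref_cursor + length,
                        sv_length=length,
                        haplotype=segment.haplotype,
                        origin="intra",
                        query_name=segment.query_name,
                        evidence_span=segment.query_span,
                    )
                )
            ref_cursor += length
        # H consumes neither the stored sequence nor the reference
    return out


def _breakend_pair(a: AlignmentSegment, b: AlignmentSegment) -> List[SvSignature]:
    """Reciprocal BND signatures for the junction between two query-adjacent segments."""
    if a.strand == "+":
        pos_a, dir_a = a.ref_end - 1, "right"
    else:
        pos_a, dir_a = a.ref_start, "left"
    if b.strand == "+":
        pos_b, dir_b = b.ref_start, "left"
    else:
        pos_b, dir_b = b.ref_end - 1, "right"
    adjacency = BreakendAdjacency(a.ref_name, pos_a, dir_a, b.ref_name, pos_b, dir_b)
    span = a.query_span + b.query_span
    common = dict(
        sv_type="BND",
        sv_length=0,
        haplotype=a.haplotype,
        origin="inter",
        query_name=a.query_name,
        evidence_span=span,
    )
    return [
        SvSignature(ref_name=a.ref_name, start=pos_a, end=pos_a, adjacency=adjacency, **common),
        SvSignature(
            ref_name=b.ref_name, start=pos_b, end=pos_b, adjacency=adjacency.reciprocal(), **common
        ),
    ]


def classify_segment_pair(
    a: AlignmentSegment, b: AlignmentSegment, params: Parameters
) -> List[SvSignature]:
    """Classify the discordancy between two query-consecutive segments.

    ``a`` must precede ``b`` on the forward-oriented contig. Same-chromosome,
    equal-strand pairs yield DEL / INS / replacement (both) / tandem
    duplication depending on the signs and sizes of the reference and query
    gaps; orientation switches and long-range or inter-chromosomal jumps
    yield a reciprocal breakend pair.
    """
    q_gap = b.query_start - a.query_end
    if q_gap < -params.query_gap_tolerance:
        return []  # implausibly large query overlap: void the pair
    q_gap = max(q_gap, 0)

    same_chrom = a.ref_name == b.ref_name
    if not same_chrom or a.strand != b.strand:
        return _breakend_pair(a, b)

    forward = a.strand == "+"
    r_gap = (b.ref_start - a.ref_end) if forward else (a.ref_start - b.ref_end)
    if abs(r_gap) > params.max_sv_size:
        return _breakend_pair(a, b)

    del_ok = params.min_sv_size <= r_gap <= params.max_sv_size
    ins_ok = q_gap >= params.min_sv_size

    def del_signature() -> SvSignature:
        start = a.ref_end if forward else b.ref_end
        return SvSignature(
            sv_type="DEL",
            ref_name=a.ref_name,
            start=start,
            end=start + r_gap,
            sv_length=r_gap,
            haplotype=a.haplotype,
            origin="inter",
            query_name=a.query_name,
            evidence_span=a.query_span + b.query_span,
        )

    def ins_signature() -> SvSignature:
        anchor = a.ref_end if forward else b.ref_end
        gap_bases = _forward_query_bases(a, a.query_end, b.query_start) or _forward_query_bases(
            b, a.query_end, b.query_start
        )
        alt = gap_bases if forward else reverse_complement(gap_bases)
        return SvSignature(
            sv_type="INS",
            ref_name=a.ref_name,
            start=anchor,
            end=anchor,
            sv_length=q_gap,
            alt_sequence=alt,
            haplotype=a.haplotype,
            origin="inter",
            query_name=a.query_name,
            evidence_span=a.query_span + b.query_span,
        )

    if del_ok and q_gap <= params.query_gap_tolerance:
        return [del_signature()]
    if ins_ok and abs(r_gap) <= params.reference_gap_tolerance:
        return [ins_signature()]
    if del_ok and ins_ok:  # replacement: reference span swapped for novel sequence
        return [del_signature(), ins_signature()]
    if r_gap <= -params.min_sv_size and q_gap <= params.query_gap_tolerance:
        start = b.ref_start if forward else a.ref_start
        end = a.ref_end if forward else b.ref_end
        return [
            SvSignature(
                sv_type="DUP_TANDEM",
                ref_name=a.ref_name,
                start=start,
                end=end,
                sv_length=end - start,
                haplotype=a.haplotype,
                origin="inter",
                query_name=a.query_name,
                evidence_span=a.query_span + b.query_span,
            )
        ]
    return []


def _query_contiguous(left: AlignmentSegment, right: AlignmentSegment, tol: int) -> bool:
    return abs(right.query_start - left.query_end) <= tol


def _analyze_triples_impl(
    segments: Sequence[AlignmentSegment], params: Parameters
) -> Tuple[List[SvSignature], Set[Tuple[int, int]]]:
    """Scan consecutive (A, B, C) windows for inversions and interspersed
    duplications; returns signatures plus the consumed adjacent-pair indices."""
    sigs: List[SvSignature] = []
    consumed: Set[Tuple[int, int]] = set()
    tol = params.reference_gap_tolerance
    for i in range(len(segments) - 2):
        a, b, c = segments[i], segments[i + 1], segments[i + 2]
        if a.ref_name != c.ref_name or a.strand != c.strand:
            continue
        if not (
            _query_contiguous(a, b, params.query_gap_tolerance)
            and _query_contiguous(b, c, params.query_gap_tolerance)
        ):
            continue
        forward = a.strand == "+"
        span = a.query_span + b.query_span + c.query_span

        # Inversion: B on the opposite strand, filling the A-C reference gap.
        inv_geometry = (
            b.ref_name == a.ref_name
            and b.strand != a.strand
            and (
                (forward and abs(b.ref_start - a.ref_end) <= tol and abs(c.ref_start - b.ref_end) <= tol)
                or (not forward and abs(b.ref_start - c.ref_end) <= tol and abs(a.ref_start - b.ref_end) <= tol)
            )
        )
        if inv_geometry:
            length = b.ref_end - b.ref_start
            if length >= params.min_sv_size:
                sigs.append(
                    SvSignature(
                        sv_type="INV",
                        ref_name=b.ref_name,
                        start=b.ref_start,
                        end=b.ref_end,
                        sv_length=length,
                        haplotype=a.haplotype,
                        origin="inter",
                        query_name=a.query_name,
                        evidence_span=span,
                    )
                )
                consumed.add((i, i + 1))
                consumed.add((i + 1, i + 2))
            continue

        # Interspersed duplication: A and C collinear (the inserted copy
        # consumes no reference), B mapping to a distant source locus.
        anchor = a.ref_end if forward else a.ref_start
        collinear = (
            abs(c.ref_start - a.ref_end) <= tol if forward else abs(a.ref_start - c.ref_end) <= tol
        )
        if not collinear:
            continue
        distant = b.ref_name != a.ref_name or (
            b.ref_start > anchor + params.max_sv_size or b.ref_end < anchor - params.max_sv_size
        ) or (b.ref_end <= anchor - tol or b.ref_start >= anchor + tol)
        if not distant or b.query_span < params.min_sv_size:
            continue
        copy_bases = _forward_query_bases(b, b.query_start, b.query_end)
        alt = copy_bases if forward else reverse_complement(copy_bases)
        sigs.append(
            SvSignature(
                sv_type="DUP_INT",
                ref_name=a.ref_name,
                start=anchor,
                end=anchor,
                sv_length=b.ref_end - b.ref_start,
                alt_sequence=alt,
                source_interval=(b.ref_name, b.ref_start, b.ref_end),
                haplotype=a.haplotype,
                origin="inter",
                query_name=a.query_name,
                evidence_span=span,
            )
        )
        consumed.add((i, i + 1))
        consumed.add((i + 1, i + 2))
    return sigs, consumed


def analyze_segment_triples(
    segments: Sequence[AlignmentSegment], params: Parameters
) -> List[SvSignature]:
    """Public triple analysis; see :func:`collect` for the pair bookkeeping."""
    return _analyze_triples_impl(segments, params)[0]


def _attach_full_query_sequence(group: List[AlignmentSegment]) -> None:
    full: Optional[str] = None
    for seg in group:
        seq = seg.query_sequence
        if seq and len(seq) == seg.query_length:
            full = seq if seg.strand == "+" else reverse_complement(seq)
            break
    if full is not None:
        for seg in group:
            seg.full_query_sequence = full


def collect(segments: Iterable[AlignmentSegment], params: Parameters) -> List[SvSignature]:
    """Run signature extraction over a stream of alignment segments.

    Segments are grouped by contig and sorted along the forward contig; every
    record contributes intra-alignment signatures, every group is scanned for
    three-segment geometries, and every query-adjacent pair not consumed by a
    triple is classified for two-segment discordancies.
    """
    groups: dict = {}
    order: List[str] = []
    for seg in segments:
        if seg.query_name not in groups:
            groups[seg.query_name] = []
            order.append(seg.query_name)
        groups[seg.query_name].append(seg)

    signatures: List[SvSignature] = []
    for name in order:
        group = sorted(groups[name], key=lambda s: (s.query_start, s.query_end))
        _attach_full_query_sequence(group)
        for seg in group:
            signatures.extend(extract_intra_signatures(seg, params))
        triple_sigs, consumed = _analyze_triples_impl(group, params)
        signatures.extend(triple_sigs)
        for i in range(len(group) - 1):
            if (i, i + 1) in consumed:
                continue
            signatures.extend(classify_segment_pair(group[i], group[i + 1], params))
    return signatures
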