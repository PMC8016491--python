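"""Reading and normalizing contig-to-reference alignments.

Assembly aligners report split contigs as one primary plus several
supplementary records, the latter usually hard-clipped. To reason about the
order of split segments along a contig we map every record back onto the
full-length forward-oriented contig using its clip lengths.
"""
from __future__ import annotations

import logging
from typing import Iterator, Optional

import pysam

from .model import AlignmentSegment

logger = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=XB"
_CLIP_OPS = frozenset("SH")
_QUERY_ALIGNED_OPS = frozenset("M=XI")


class MalformedCigarError(ValueError):
    """Raised for CIGARs with clips in the interior."""


def query_interval_on_forward_strand(cigar, strand: str):
    """Locate the aligned interval of a record on the forward contig.

    Returns ``(query_start, query_end, query_length)`` where the coordinates
    are 0-based half-open on the full-length forward-oriented contig and
    ``query_length`` includes clipped bases. For reverse-strand alignments the
    clip lengths swap roles: the trailing clip in alignment orientation is the
    leading part of the contig.
    """
    if not cigar:
        raise MalformedCigarError("empty CIGAR")
    i, j = 0, len(cigar)
    lead = trail = 0
    while i < j and cigar[i][0] in _CLIP_OPS:
        lead += cigar[i][1]
        i += 1
    while j > i and cigar[j - 1][0] in _CLIP_OPS:
        trail += cigar[j - 1][1]
        j -= 1
    aligned = 0
    for op, length in cigar[i:j]:
        if op in _CLIP_OPS:
            raise MalformedCigarError("clip operation inside CIGAR")
        if op in _QUERY_ALIGNED_OPS:
            aligned += length
    query_length = lead + aligned + trail
    query_start = lead if strand == "+" else trail
    return query_start, query_start + aligned, query_length


def segment_from_pysam(aln: pysam.AlignedSegment, haplotype: Optional[int] = None) -> AlignmentSegment:
    """Convert a mapped pysam record into an :class:`AlignmentSegment`."""
    cigar = [(_CIGAR_OPS[op], length) for op, length in aln.cigartuples]
    strand = "-" if aln.is_reverse else "+"
    query_start, query_end, query_length = query_interval_on_forward_strand(cigar, strand)
    return AlignmentSegment(
        query_name=aln.query_name,
        query_start=query_start,
        query_end=query_end,
        query_length=query_length,
        ref_name=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand=strand,
        cigar=cigar,
        query_sequence=aln.query_sequence,
        haplotype=haplotype,
        mapq=aln.mapping_quality,
        is_supplementary=aln.is_supplementary,
    )


def read_alignments(path, haplotype: Optional[int] = None, min_mapq: int = 0) -> Iterator[AlignmentSegment]:
    """Stream alignment segments from a coordinate-sorted SAM/BAM file.

    Primary and supplementary records are kept; secondary and unmapped
    records are skipped (split contigs are represented as primary plus
    supplementary alignments, while secondaries are redundant placements).
    Records whose query coordinates cannot be resolved are skipped with a
    warning.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            try:
                yield segment_from_pysam(aln, haplotype=haplotype)
            except MalformedCigarError as exc:
                logger.warning(
                    "skipping record %s: unresolvable query coordinates (%s)",
                    aln.query_name,
                    exc,
                )
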