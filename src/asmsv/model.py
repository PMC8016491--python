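"""Shared data types for the assembly-based SV calling pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion to
1-based happens only when VCF records are serialized. Query coordinates always
refer to the full-length, forward-oriented contig, regardless of the strand a
segment aligned to.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SV_TYPES = ("DEL", "INS", "INV", "DUP_TANDEM", "DUP_INT", "BND")

_COMPLEMENT = str.maketrans("ACGTRYKMacgtrykmNn", "TGCAYRMKtgcayrmkNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BreakendAdjacency:
    """One novel adjacency between two genomic loci.

    ``dir1``/``dir2`` name the side of each breakend base that participates in
    the junction: ``"right"`` means the sequence left of (and including) the
    base is joined at its right side (VCF ``t[``/``t]`` records), ``"left"``
    means the sequence right of (and including) the base is joined at its left
    side (``]p]t``/``[p[t`` records). Positions are 0-based breakend bases.
    """

    chrom1: str
    pos1: int
    dir1: str
    chrom2: str
    pos2: int
    dir2: str

    def reciprocal(self) -> "BreakendAdjacency":
        return BreakendAdjacency(
            self.chrom2, self.pos2, self.dir2, self.chrom1, self.pos1, self.dir1
        )

    def canonical(self) -> "BreakendAdjacency":
        """Deterministic orientation: smaller (chrom, pos, dir) endpoint first."""
        if (self.chrom2, self.pos2, self.dir2) < (self.chrom1, self.pos1, self.dir1):
            return self.reciprocal()
        return self


@dataclass
class Parameters:
    """Tunable thresholds of the caller.

    min_sv_size:
        Smallest reported variant (bp).
    max_sv_size:
        Same-chromosome reference jumps larger than this are emitted as
        breakend pairs instead of deletions/duplications (bp).
    query_gap_tolerance:
        Largest contig-coordinate gap (or overlap) between consecutive
        alignment segments that is ignored when classifying reference gaps (bp).
    reference_gap_tolerance:
        Largest reference displacement ignored when classifying contig-side
        gaps (insertions) and when testing split-segment collinearity (bp).
    pairing_max_span_distance:
        Largest reference-position difference for two signatures from opposite
        haplotypes to be considered pairing candidates (bp).
    pairing_max_edit_fraction:
        Largest length-normalized edit distance between the haplotype
        sequences of two signatures that still allows a merge.
    """

    min_sv_size: int = 40
    max_sv_size: int = 100_000
    query_gap_tolerance: int = 50
    reference_gap_tolerance: int = 50
    pairing_max_span_distance: int = 1000
    pairing_max_edit_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.min_sv_size < 0 or self.max_sv_size < self.min_sv_size:
            raise ValueError("require 0 <= min_sv_size <= max_sv_size")


@dataclass
class AlignmentSegment:
    """One contig alignment normalized to forward-query coordinates."""

    query_name: str
    query_start: int
    query_end: int
    query_length: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    cigar: list  # [(op, length)] with op in M,=,X,I,D,S,H
    query_sequence: Optional[str] = None
    haplotype: Optional[int] = None
    mapq: int = 0
    is_supplementary: bool = False
    # Forward-oriented full contig sequence, attached during collection when a
    # record of the same contig stores it (e.g. a soft-clipped primary).
    full_query_sequence: Optional[str] = None

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class SvSignature:
    """Raw evidence for one SV from one haplotype, before merging."""

    sv_type: str
    ref_name: str
    start: int
    end: int
    sv_length: int
    alt_sequence: str = ""
    source_interval: Optional[tuple] = None  # (ref_name, start, end) for DUP_INT
    adjacency: Optional[BreakendAdjacency] = None  # BND only
    haplotype: Optional[int] = None
    origin: str = "intra"  # "intra" or "inter"
    query_name: str = ""
    evidence_span: int = 0  # query span of the supporting alignment(s)

    def position_key(self):
        return (self.ref_name, self.start, self.end, self.sv_type)


@dataclass
class SvCandidate:
    """A genotyped, possibly haplotype-merged variant call."""

    sv_type: str
    ref_name: str
    start: int
    end: int
    sv_length: int
    alt_sequence: str = ""
    source_interval: Optional[tuple] = None
    adjacency: Optional[BreakendAdjacency] = None
    genotype: str = "unknown"  # hom_alt | het | unknown
    support: list = field(default_factory=list)


@dataclass
class TruthRecord:
    """An SV implanted into the synthetic genome, in reference coordinates."""

    sv_type: str
    ref_name: str
    start: int
    end: int
    sv_length: int
    zygosity: str  # hom | het_hap1 | het_hap2
    alt_sequence: str = ""
    source_interval: Optional[tuple] = None
    adjacency: Optional[BreakendAdjacency] = None

    def carried_by(self, haplotype: int) -> bool:
        return self.zygosity == "hom" or self.zygosity == f"het_hap{haplotype}"
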