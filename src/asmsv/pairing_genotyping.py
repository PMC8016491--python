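"""PAIR and GENOTYPE steps.

Signatures extracted separately from the two haplotypes of a diploid
assembly are compared by the edit distance of their haplotype sequences and
paired up when sufficiently similar. A paired signature means both parental
haplotypes carry the variant (homozygous); an unpaired signature means only
one does (heterozygous). Haploid assemblies skip both steps.
"""
from __future__ import annotations

import math
from dataclasses import replace
from typing import List, Sequence, Tuple

import edlib

from .model import Parameters, SvCandidate, SvSignature

__all__ = [
    "edit_distance",
    "signature_similarity",
    "pair_and_genotype",
    "dedup_within_haplotype",
    "candidates_from_signatures",
]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs (edlib's NW mode)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _sequence_distance(s1: SvSignature, s2: SvSignature) -> float:
    """Normalized distance between the haplotype sequences of two signatures.

    Insertion-type signatures carry their inserted bases, so a true edit
    distance is computed. Deletion-type signatures (DEL/INV/DUP_TANDEM) have
    no stored variant sequence; the relative length difference stands in,
    which equals the normalized edit distance of the affected reference
    spans' lengths.
    """
    if s1.sv_type in ("INS", "DUP_INT") and s1.alt_sequence and s2.alt_sequence:
        denom = max(len(s1.alt_sequence), len(s2.alt_sequence))
        return edit_distance(s1.alt_sequence, s2.alt_sequence) / denom if denom else 0.0
    denom = max(s1.sv_length, s2.sv_length)
    return abs(s1.sv_length - s2.sv_length) / denom if denom else 0.0


def signature_similarity(
    s1: SvSignature, s2: SvSignature, params: Parameters
) -> Tuple[bool, float]:
    """Decide whether two signatures may be merged; return the distance too."""
    if s1.sv_type != s2.sv_type:
        return False, math.inf
    if s1.sv_type == "BND":
        a1, a2 = s1.adjacency.canonical(), s2.adjacency.canonical()
        ok = (
            a1.chrom1 == a2.chrom1
            and a1.chrom2 == a2.chrom2
            and a1.dir1 == a2.dir1
            and a1.dir2 == a2.dir2
            and abs(a1.pos1 - a2.pos1) <= params.pairing_max_span_distance
            and abs(a1.pos2 - a2.pos2) <= params.pairing_max_span_distance
        )
        return (True, 0.0) if ok else (False, math.inf)
    if s1.ref_name != s2.ref_name:
        return False, math.inf
    if abs(s1.start - s2.start) > params.pairing_max_span_distance:
        return False, math.inf
    distance = _sequence_distance(s1, s2)
    return distance <= params.pairing_max_edit_fraction, distance


def _candidate(rep: SvSignature, genotype: str, support: List[SvSignature]) -> SvCandidate:
    return SvCandidate(
        sv_type=rep.sv_type,
        ref_name=rep.ref_name,
        start=rep.start,
        end=rep.end,
        sv_length=rep.sv_length,
        alt_sequence=rep.alt_sequence,
        source_interval=rep.source_interval,
        adjacency=rep.adjacency,
        genotype=genotype,
        support=support,
    )


def _candidate_sort_key(c: SvCandidate):
    return (c.ref_name, c.start, c.end, c.sv_type, c.sv_length)


def pair_and_genotype(
    hap1: Sequence[SvSignature], hap2: Sequence[SvSignature], params: Parameters
) -> List[SvCandidate]:
    """Greedy one-to-one cross-haplotype matching by ascending edit distance.

    Ties are broken by ascending reference position, then by haplotype-1
    input order, which makes the matching fully deterministic. Matched pairs
    become homozygous candidates (coordinates from the haplotype-1
    representative); unmatched signatures become heterozygous candidates.
    """
    edges = []
    for i, s1 in enumerate(hap1):
        for j, s2 in enumerate(hap2):
            ok, distance = signature_similarity(s1, s2, params)
            if ok:
                edges.append((distance, s1.start, i, j))
    edges.sort()
    matched1: dict = {}
    used2: set = set()
    for _, _, i, j in edges:
        if i in matched1 or j in used2:
            continue
        matched1[i] = j
        used2.add(j)

    candidates: List[SvCandidate] = []
    for i, s1 in enumerate(hap1):
        if i in matched1:
            s2 = hap2[matched1[i]]
            candidates.append(_candidate(s1, "hom_alt", [s1, s2]))
        else:
            candidates.append(_candidate(s1, "het", [s1]))
    for j, s2 in enumerate(hap2):
        if j not in used2:
            candidates.append(_candidate(s2, "het", [s2]))
    candidates.sort(key=_candidate_sort_key)
    return candidates


def candidates_from_signatures(
    signatures: Sequence[SvSignature], genotype: str = "unknown"
) -> List[SvCandidate]:
    """Wrap signatures as candidates without pairing (haploid pipeline)."""
    out = [_candidate(s, genotype, [s]) for s in signatures]
    out.sort(key=_candidate_sort_key)
    return out


def _canonicalize_bnd(sig: SvSignature) -> SvSignature:
    if sig.sv_type != "BND" or sig.adjacency is None:
        return sig
    canon = sig.adjacency.canonical()
    if canon == sig.adjacency:
        return sig
    return replace(sig, ref_name=canon.chrom1, start=canon.pos1, end=canon.pos1, adjacency=canon)


def dedup_within_haplotype(
    signatures: Sequence[SvSignature], params: Parameters
) -> List[SvSignature]:
    """Collapse redundant signatures reported by overlapping contigs.

    Signatures that would pass :func:`signature_similarity` against each
    other (the different-haplotype precondition ignored) are clustered
    transitively; the representative is the one with the longest supporting
    alignment (ties: leftmost, then input order). Breakend mates are
    canonicalized first, so the two reciprocal halves of one adjacency
    collapse into a single representative signature.
    """
    sigs = [_canonicalize_bnd(s) for s in signatures]
    clusters: List[List[SvSignature]] = []
    for sig in sigs:
        home = None
        for cluster in clusters:
            if any(signature_similarity(sig, member, params)[0] for member in cluster):
                home = cluster
                break
        if home is None:
            clusters.append([sig])
        else:
            home.append(sig)
    out: List[SvSignature] = []
    for cluster in clusters:
        rep = min(cluster, key=lambda s: (-s.evidence_span, s.ref_name, s.start))
        out.append(rep)
    out.sort(key=lambda s: (s.ref_name, s.start, s.end, s.sv_type))
    return out
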