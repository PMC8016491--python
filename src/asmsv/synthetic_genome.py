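"""Synthetic diploid genomes with implanted SVs and analytically built alignments.

This module emulates the inputs of the caller without running an aligner: a
random reference, two haplotype sequence sets carrying implanted variants of
all six classes with controlled zygosity, and the corresponding SAM records
constructed from the implant arithmetic — gapped CIGARs for intra-alignment
evidence and split (primary + supplementary) records for inter-alignment
evidence. A simple truvari-like matcher scores calls against the implant
truth.

What is emulated: guard-separated, fully resolved SVs on error-free contigs,
optionally with point-mutation divergence between the haplotypes. What is
not: assembly errors, repeat-mediated placement, nested events.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .model import BreakendAdjacency, SvCandidate, TruthRecord, reverse_complement

__all__ = [
    "generate_reference",
    "implant_svs",
    "emit_alignments",
    "evaluate_calls",
    "EvaluationMetrics",
    "write_fasta",
    "write_sam",
    "write_truth_tsv",
    "make_benchmark_fixture",
    "DEFAULT_SV_MIX",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Standard fixture mix: (sv_type, (min_len, max_len), count, hom_fraction).
DEFAULT_SV_MIX = (
    ("DEL", (50, 5000), 30, 0.5),
    ("INS", (50, 5000), 30, 0.5),
    ("INV", (50, 5000), 6, 0.5),
    ("DUP_TANDEM", (50, 5000), 6, 0.5),
    ("DUP_INT", (50, 5000), 4, 0.5),
    ("BND", None, 4, 0.5),
)


def generate_reference(n_chroms: int, chrom_length: int, seed: int) -> Dict[str, str]:
    """Random genome with uniform base composition; chromosomes chr1..chrN."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    rng = np.random.default_rng(seed)
    return {
        f"chr{i + 1}": rng.choice(_BASES, size=chrom_length).tobytes().decode()
        for i in range(n_chroms)
    }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for p in hits:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


class _Reserver:
    """Non-overlapping placement with guard distances, by rejection sampling."""

    def __init__(self, genome: Dict[str, str], guard: int, rng: np.random.Generator):
        self.lengths = {name: len(seq) for name, seq in genome.items()}
        self.names = list(genome)
        self.guard = guard
        self.rng = rng
        self.taken: Dict[str, List[Tuple[int, int]]] = {name: [] for name in genome}
        total = sum(self.lengths.values())
        self.weights = np.array([self.lengths[n] / total for n in self.names])

    def _free(self, chrom: str, lo: int, hi: int) -> bool:
        if lo < self.guard or hi > self.lengths[chrom] - self.guard:
            return False
        return all(hi + self.guard <= a or lo - self.guard >= b for a, b in self.taken[chrom])

    def reserve(self, span: int, chrom: Optional[str] = None, tries: int = 2000) -> Tuple[str, int]:
        for _ in range(tries):
            name = chrom or self.rng.choice(self.names, p=self.weights)
            limit = self.lengths[name] - span - self.guard
            if limit <= self.guard:
                continue
            start = int(self.rng.integers(self.guard, limit))
            if self._free(name, start, start + span):
                self.taken[name].append((start, start + span))
                return name, start
        raise ValueError("cannot place SV: genome too small for the requested spec")


def implant_svs(
    genome: Dict[str, str],
    sv_spec: Sequence[Tuple] = DEFAULT_SV_MIX,
    seed: int = 0,
    guard: int = 750,
    bnd_flank: int = 2000,
    divergence_rate: float = 0.0,
) -> Tuple[Dict[str, str], Dict[str, str], List[TruthRecord]]:
    """Implant SVs into two haplotypes of ``genome``.

    ``sv_spec`` entries are ``(sv_type, (min_len, max_len), count,
    hom_fraction)``; lengths are drawn log-uniformly. Homozygous events go to
    both haplotypes at identical reference loci, heterozygous events to one
    (chosen uniformly). Breakend events do not alter the linear haplotype
    sequences; they are realized as fusion contigs by
    :func:`emit_alignments`. ``divergence_rate`` adds independent point
    mutations to each haplotype at half the given per-base rate, so the
    expected divergence *between* haplotypes matches the rate.
    """
    rng = np.random.default_rng(seed)
    reserver = _Reserver(genome, guard, rng)
    truth: List[TruthRecord] = []

    def draw_length(size_range) -> int:
        lo, hi = size_range
        return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))

    def draw_zygosity(hom_fraction: float) -> str:
        if rng.random() < hom_fraction:
            return "hom"
        return "het_hap1" if rng.random() < 0.5 else "het_hap2"

    for sv_type, size_range, count, hom_fraction in sv_spec:
        for _ in range(count):
            zygosity = draw_zygosity(hom_fraction)
            if sv_type in ("DEL", "INV", "DUP_TANDEM"):
                length = draw_length(size_range)
                chrom, start = reserver.reserve(length)
                truth.append(
                    TruthRecord(sv_type, chrom, start, start + length, length, zygosity)
                )
            elif sv_type == "INS":
                length = draw_length(size_range)
                chrom, anchor = reserver.reserve(1)
                truth.append(
                    TruthRecord(
                        "INS", chrom, anchor, anchor, length, zygosity,
                        alt_sequence=_random_seq(rng, length),
                    )
                )
            elif sv_type == "DUP_INT":
                length = draw_length(size_range)
                src_chrom, src_start = reserver.reserve(length)
                chrom, anchor = reserver.reserve(1)
                truth.append(
                    TruthRecord(
                        "DUP_INT", chrom, anchor, anchor, length, zygosity,
                        alt_sequence=genome[src_chrom][src_start : src_start + length],
                        source_interval=(src_chrom, src_start, src_start + length),
                    )
                )
            elif sv_type == "BND":
                if len(genome) < 2:
                    raise ValueError("inter-chromosomal adjacencies need >= 2 chromosomes")
                c1, p1 = reserver.reserve(2 * bnd_flank)
                other = [n for n in genome if n != c1]
                c2 = other[int(rng.integers(len(other)))]
                c2, p2 = reserver.reserve(2 * bnd_flank, chrom=c2)
                pos1, pos2 = p1 + bnd_flank, p2 + bnd_flank
                dir1 = "right" if rng.random() < 0.5 else "left"
                dir2 = "left" if rng.random() < 0.5 else "right"
                adjacency = BreakendAdjacency(c1, pos1, dir1, c2, pos2, dir2)
                truth.append(
                    TruthRecord("BND", c1, pos1, pos1, 0, zygosity, adjacency=adjacency)
                )
            else:
                raise ValueError(f"unknown SV type in spec: {sv_type!r}")

    haplotypes: List[Dict[str, str]] = []
    for hap in (1, 2):
        hap_genome: Dict[str, str] = {}
        for chrom, seq in genome.items():
            events = [
                t for t in truth
                if t.ref_name == chrom and t.carried_by(hap) and t.sv_type != "BND"
            ]
            for t in sorted(events, key=lambda t: t.start, reverse=True):
                if t.sv_type == "DEL":
                    seq = seq[: t.start] + seq[t.end :]
                elif t.sv_type == "INS":
                    seq = seq[: t.start] + t.alt_sequence + seq[t.start :]
                elif t.sv_type == "INV":
                    seq = seq[: t.start] + reverse_complement(seq[t.start : t.end]) + seq[t.end :]
                elif t.sv_type == "DUP_TANDEM":
                    seq = seq[: t.end] + seq[t.start : t.end] + seq[t.end :]
                elif t.sv_type == "DUP_INT":
                    seq = seq[: t.start] + t.alt_sequence + seq[t.start :]
            hap_genome[chrom] = _mutate(seq, divergence_rate / 2.0, rng)
        haplotypes.append(hap_genome)
    return haplotypes[0], haplotypes[1], truth


# ---------------------------------------------------------------------------
# Analytic alignment construction


@dataclass
class _Seg:
    """One planned alignment segment in forward-query coordinates."""

    chrom: str
    strand: str
    ref_start: int
    q_start: int
    ops: List[List] = field(default_factory=list)  # [[op, length], ...] forward order

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.ops if op in ("M", "D"))

    @property
    def q_end(self) -> int:
        return self.q_start + sum(l for op, l in self.ops if op in ("M", "I"))


def _plan_chromosome(chrom: str, ref_len: int, events: List[TruthRecord], style: str):
    """Lay out alignment segments for one haplotype chromosome.

    Walks the reference and the implanted events in lockstep. In ``gapped``
    style, deletions and insertions stay inside one record as D/I operations;
    in ``split`` style they break the record. Inversions, duplications and
    interspersed copies always produce split segments, since no single gapped
    record can encode them.
    """
    segs: List[_Seg] = []
    state = {"ops": [], "seg_r": 0, "seg_q": 0, "r": 0, "q": 0}

    def close():
        if state["ops"]:
            segs.append(_Seg(chrom, "+", state["seg_r"], state["seg_q"], state["ops"]))
        state["ops"] = []

    def open_at(new_r: int, new_q: int):
        state["seg_r"], state["seg_q"] = new_r, new_q
        state["r"], state["q"] = new_r, new_q

    def match(length: int):
        if length > 0:
            if state["ops"] and state["ops"][-1][0] == "M":
                state["ops"][-1][1] += length
            else:
                state["ops"].append(["M", length])
            state["r"] += length
            state["q"] += length

    for t in sorted(events, key=lambda t: t.start):
        match(t.start - state["r"])
        if t.sv_type == "DEL":
            length = t.end - t.start
            if style == "gapped":
                state["ops"].append(["D", length])
                state["r"] += length
            else:
                close()
                open_at(t.end, state["q"])
        elif t.sv_type == "INS":
            if style == "gapped":
                state["ops"].append(["I", t.sv_length])
                state["q"] += t.sv_length
            else:
                close()
                open_at(state["r"], state["q"] + t.sv_length)
        elif t.sv_type == "INV":
            length = t.end - t.start
            close()
            segs.append(_Seg(chrom, "-", t.start, state["q"], [["M", length]]))
            open_at(t.end, state["q"] + length)
        elif t.sv_type == "DUP_TANDEM":
            match(t.end - state["r"])  # finish the original copy
            close()
            open_at(t.start, state["q"])  # re-enter at the duplicated span
        elif t.sv_type == "DUP_INT":
            src_chrom, src_start, src_end = t.source_interval
            length = src_end - src_start
            close()
            segs.append(_Seg(src_chrom, "+", src_start, state["q"], [["M", length]]))
            open_at(t.start, state["q"] + length)
    match(ref_len - state["r"])
    close()
    return segs, state["q"]


def _split_seg(seg: _Seg, q_pos: int) -> Tuple[_Seg, _Seg]:
    """Split a forward segment inside an M block at forward-query position q_pos."""
    r, q = seg.ref_start, seg.q_start
    for k, (op, length) in enumerate(seg.ops):
        q_step = length if op in ("M", "I") else 0
        r_step = length if op in ("M", "D") else 0
        if op == "M" and q < q_pos < q + length:
            offset = q_pos - q
            left = _Seg(seg.chrom, "+", seg.ref_start, seg.q_start,
                        [list(o) for o in seg.ops[:k]] + [["M", offset]])
            right = _Seg(seg.chrom, "+", r + offset, q_pos,
                         [["M", length - offset]] + [list(o) for o in seg.ops[k + 1:]])
            return left, right
        r, q = r + r_step, q + q_step
    raise ValueError("split position not inside an M block")


def _cut_into_contigs(segs: List[_Seg], total_q: int, contig_length: Optional[int], margin: int = 200):
    """Return [(q_offset, q_limit, segments)] contig windows."""
    if not contig_length or contig_length >= total_q:
        return [(0, total_q, segs)]
    cuts: List[int] = []
    target = contig_length
    while target < total_q - contig_length // 2:
        placed = None
        for seg in segs:
            if seg.strand != "+":
                continue
            r, q = seg.ref_start, seg.q_start
            for op, length in seg.ops:
                if op == "M" and length > 2 * margin:
                    lo, hi = q + margin, q + length - margin
                    if lo <= target < hi:
                        placed = target
                    elif target < lo <= hi and (not cuts or lo > cuts[-1] + margin):
                        placed = placed if placed is not None else lo
                if op in ("M", "I"):
                    q += length
                if op in ("M", "D"):
                    r += length
            if placed is not None:
                break
        if placed is not None and (not cuts or placed > cuts[-1]):
            cuts.append(placed)
        target += contig_length

    for cut in cuts:
        new_segs: List[_Seg] = []
        for seg in segs:
            if seg.strand == "+" and seg.q_start < cut < seg.q_end:
                left, right = _split_seg(seg, cut)
                new_segs.extend([left, right])
            else:
                new_segs.append(seg)
        segs = new_segs

    bounds = [0] + cuts + [total_q]
    contigs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        window = [s for s in segs if lo <= s.q_start and s.q_end <= hi]
        contigs.append((lo, hi, window))
    return contigs


_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4, "H": 5}


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    seg: _Seg,
    q_offset: int,
    contig_seq: str,
    primary: bool,
) -> pysam.AlignedSegment:
    qlen = len(contig_seq)
    q_start, q_end = seg.q_start - q_offset, seg.q_end - q_offset
    if seg.strand == "+":
        lead, trail = q_start, qlen - q_end
        ops = seg.ops
    else:
        lead, trail = qlen - q_end, q_start
        ops = list(reversed(seg.ops))
    clip = "S" if primary else "H"
    cigar = ([(clip, lead)] if lead else []) + [tuple(o) for o in ops] + (
        [(clip, trail)] if trail else []
    )
    if primary:
        seq = contig_seq if seg.strand == "+" else reverse_complement(contig_seq)
    else:
        piece = contig_seq[q_start:q_end]
        seq = piece if seg.strand == "+" else reverse_complement(piece)
    record = pysam.AlignedSegment(header)
    record.query_name = qname
    record.flag = (0 if primary else 2048) | (16 if seg.strand == "-" else 0)
    record.reference_id = header.references.index(seg.chrom)
    record.reference_start = seg.ref_start
    record.mapping_quality = 60
    record.query_sequence = seq
    record.cigartuples = [(_OP_CODE[op], length) for op, length in cigar]
    return record


def emit_alignments(
    haplotypes: Dict[int, Dict[str, str]],
    truth: List[TruthRecord],
    reference: Dict[str, str],
    contig_length: Optional[int] = None,
    style: str = "gapped",
    bnd_flank: int = 2000,
):
    """Construct ideal SAM records for each haplotype's contigs.

    Returns ``(header, {haplotype: [pysam.AlignedSegment, ...]})`` with
    records coordinate-sorted. Primary records are soft-clipped and carry the
    full contig sequence; supplementary records are hard-clipped. Breakend
    truth events become dedicated fusion contigs joining the flanks of the
    two adjacency endpoints.
    """
    if style not in ("gapped", "split"):
        raise ValueError("style must be 'gapped' or 'split'")
    names = list(reference)
    header = pysam.AlignmentHeader.from_references(names, [len(reference[n]) for n in names])

    out: Dict[int, List[pysam.AlignedSegment]] = {}
    for hap, hap_genome in haplotypes.items():
        records: List[pysam.AlignedSegment] = []
        for chrom in names:
            if chrom not in hap_genome:
                continue
            events = [
                t for t in truth
                if t.ref_name == chrom and t.carried_by(hap) and t.sv_type != "BND"
            ]
            segs, total_q = _plan_chromosome(chrom, len(reference[chrom]), events, style)
            hap_seq = hap_genome[chrom]
            if total_q != len(hap_seq):
                raise ValueError(
                    f"planned contig length {total_q} != haplotype sequence {len(hap_seq)}"
                )
            for idx, (lo, hi, window) in enumerate(
                _cut_into_contigs(segs, total_q, contig_length)
            ):
                qname = f"hap{hap}_{chrom}_{idx}"
                contig_seq = hap_seq[lo:hi]
                primary_idx = max(
                    range(len(window)), key=lambda k: (window[k].q_end - window[k].q_start, -k)
                )
                for k, seg in enumerate(window):
                    records.append(
                        _make_record(header, qname, seg, lo, contig_seq, k == primary_idx)
                    )
        # fusion contigs realizing the novel adjacencies
        bnd_events = [t for t in truth if t.sv_type == "BND" and t.carried_by(hap)]
        for n, t in enumerate(bnd_events):
            adj = t.adjacency
            f = bnd_flank
            if adj.dir1 == "right":
                seg1 = _Seg(adj.chrom1, "+", adj.pos1 + 1 - f, 0, [["M", f]])
                bases1 = reference[adj.chrom1][adj.pos1 + 1 - f : adj.pos1 + 1]
            else:
                seg1 = _Seg(adj.chrom1, "-", adj.pos1, 0, [["M", f]])
                bases1 = reverse_complement(reference[adj.chrom1][adj.pos1 : adj.pos1 + f])
            if adj.dir2 == "left":
                seg2 = _Seg(adj.chrom2, "+", adj.pos2, f, [["M", f]])
                bases2 = reference[adj.chrom2][adj.pos2 : adj.pos2 + f]
            else:
                seg2 = _Seg(adj.chrom2, "-", adj.pos2 + 1 - f, f, [["M", f]])
                bases2 = reverse_complement(reference[adj.chrom2][adj.pos2 + 1 - f : adj.pos2 + 1])
            contig_seq = bases1 + bases2
            qname = f"hap{hap}_fusion_{n}"
            records.append(_make_record(header, qname, seg1, 0, contig_seq, True))
            records.append(_make_record(header, qname, seg2, 0, contig_seq, False))
        records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
        out[hap] = records
    return header, out


def write_sam(path, header: pysam.AlignmentHeader, records: List[pysam.AlignedSegment]) -> None:
    with pysam.AlignmentFile(str(path), "wh", header=header) as handle:
        for record in records:
            handle.write(record)


def write_fasta(path, sequences: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_truth_tsv(path, truth: List[TruthRecord]) -> None:
    with open(path, "w") as handle:
        handle.write("sv_type\tref_name\tstart\tend\tsv_length\tzygosity\tsource_interval\n")
        for t in truth:
            src = (
                f"{t.source_interval[0]}:{t.source_interval[1]}-{t.source_interval[2]}"
                if t.source_interval
                else "."
            )
            handle.write(
                f"{t.sv_type}\t{t.ref_name}\t{t.start}\t{t.end}\t{t.sv_length}\t{t.zygosity}\t{src}\n"
            )


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    gt_checked: int
    gt_correct: int
    genotype_concordance: float
    zero_denominators: List[str] = field(default_factory=list)


def _genotype_matches(call_gt: str, zygosity: str) -> bool:
    if call_gt == "hom_alt":
        return zygosity == "hom"
    if call_gt == "het":
        return zygosity.startswith("het_")
    return False


def _call_matches_truth(
    call: SvCandidate, t: TruthRecord, pos_tol: int, len_frac: float
) -> bool:
    if call.sv_type != t.sv_type:
        return False
    if call.sv_type == "BND":
        if call.adjacency is None or t.adjacency is None:
            return False
        a, b = call.adjacency.canonical(), t.adjacency.canonical()
        return (
            a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
            and a.dir1 == b.dir1 and a.dir2 == b.dir2
            and abs(a.pos1 - b.pos1) <= pos_tol and abs(a.pos2 - b.pos2) <= pos_tol
        )
    if call.ref_name != t.ref_name or abs(call.start - t.start) > pos_tol:
        return False
    denom = max(call.sv_length, t.sv_length, 1)
    return abs(call.sv_length - t.sv_length) / denom <= len_frac


def evaluate_calls(
    calls: Sequence[SvCandidate],
    truth: Sequence[TruthRecord],
    position_tolerance: int = 10,
    length_tolerance_fraction: float = 0.3,
) -> EvaluationMetrics:
    """Greedy one-to-one matching of calls to implanted truth records.

    A call matches a truth record of the same class at the same locus
    (position within ``position_tolerance``, length within
    ``length_tolerance_fraction``; breakends by adjacency endpoints).
    Genotype concordance is computed over true positives whose call carries a
    genotype (haploid calls are excluded).
    """
    unmatched = list(range(len(truth)))
    tp = fp = 0
    gt_checked = gt_correct = 0
    for call in sorted(calls, key=lambda c: (c.ref_name, c.start, c.sv_type)):
        best = None
        for idx in unmatched:
            t = truth[idx]
            if _call_matches_truth(call, t, position_tolerance, length_tolerance_fraction):
                err = abs(call.start - t.start)
                if best is None or err < best[0]:
                    best = (err, idx)
        if best is None:
            fp += 1
            continue
        tp += 1
        unmatched.remove(best[1])
        t = truth[best[1]]
        if call.genotype in ("hom_alt", "het"):
            gt_checked += 1
            gt_correct += int(_genotype_matches(call.genotype, t.zygosity))
    fn = len(unmatched)

    zero: List[str] = []
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision, zero = 0.0, zero + ["precision"]
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall, zero = 0.0, zero + ["recall"]
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if gt_checked:
        concordance = gt_correct / gt_checked
    else:
        concordance, zero = 0.0, zero + ["genotype_concordance"]
    return EvaluationMetrics(
        tp, fp, fn, precision, recall, f1, gt_checked, gt_correct, concordance, zero
    )


def make_benchmark_fixture(
    seed: int,
    divergence_rate: float = 0.0,
    style: str = "gapped",
    n_chroms: int = 2,
    chrom_length: int = 250_000,
    sv_spec: Sequence[Tuple] = DEFAULT_SV_MIX,
    contig_length: Optional[int] = None,
):
    """Build the standard evaluation fixture: genome, haplotypes, truth, SAMs."""
    reference = generate_reference(n_chroms, chrom_length, seed)
    hap1, hap2, truth = implant_svs(
        reference, sv_spec, seed=seed + 1, divergence_rate=divergence_rate
    )
    header, records = emit_alignments(
        {1: hap1, 2: hap2}, truth, reference, contig_length=contig_length, style=style
    )
    return {
        "reference": reference,
        "hap1": hap1,
        "hap2": hap2,
        "truth": truth,
        "header": header,
        "records": records,
    }
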