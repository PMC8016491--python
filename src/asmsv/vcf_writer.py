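"""OUTPUT step: serialize SV candidates as a sorted VCF 4.2 file.

Deletions and insertions are written sequence-resolved by default (with a
padding base, enabling sequence-aware benchmarking); inversions and
duplications are symbolic; every translocation adjacency yields two breakend
records with bracketed mate ALT alleles and MATEID cross-references.
"""
from __future__ import annotations

import datetime
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pysam

from .model import SvCandidate

__all__ = ["write_vcf", "format_record", "Reference"]

_GT = {"hom_alt": "1/1", "het": "0/1"}

_HEADER_DEFINITIONS = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant described in this record">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Origin locus of the duplicated segment (chrom:start-end, 1-based inclusive)">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
    '##ALT=<ID=DUP:INT,Description="Interspersed duplication">',
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


class Reference:
    """Uniform access to an indexed FASTA file or an in-memory genome dict."""

    def __init__(self, source):
        if isinstance(source, Reference):
            self._fasta, self._dict = source._fasta, source._dict
        elif isinstance(source, (str, Path)):
            self._fasta, self._dict = pysam.FastaFile(str(source)), None
        elif isinstance(source, pysam.FastaFile):
            self._fasta, self._dict = source, None
        else:
            self._fasta, self._dict = None, dict(source)

    @property
    def names(self) -> List[str]:
        if self._fasta is not None:
            return list(self._fasta.references)
        return list(self._dict)

    def length(self, name: str) -> int:
        if self._fasta is not None:
            return self._fasta.get_reference_length(name)
        return len(self._dict[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        if start < 0 or end > self.length(name):
            raise ValueError(f"locus {name}:{start}-{end} outside reference bounds")
        if self._fasta is not None:
            return self._fasta.fetch(name, start, end).upper()
        return self._dict[name][start:end].upper()


def _bnd_alt(ref_base: str, local_dir: str, mate_chrom: str, mate_pos1: int, mate_dir: str) -> str:
    mate = f"{mate_chrom}:{mate_pos1}"
    if local_dir == "right":
        return f"{ref_base}[{mate}[" if mate_dir == "left" else f"{ref_base}]{mate}]"
    return f"[{mate}[{ref_base}" if mate_dir == "left" else f"]{mate}]{ref_base}"


def _info_str(pairs: Sequence[Tuple[str, object]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def format_record(
    candidate: SvCandidate,
    reference: Reference,
    id_counter: dict,
    haploid_gt: str = "./1",
    symbolic_del_threshold: int = 10_000,
) -> List[Tuple[str, int, str, str]]:
    """Render one candidate as one (or, for breakends, two) VCF line(s).

    Returns ``(chrom, pos_1based, record_id, line)`` tuples so the caller can
    sort records across candidates. ``id_counter`` maps SVTYPE to the next
    ordinal and is updated in place.
    """
    reference = Reference(reference)
    c = candidate
    gt = _GT.get(c.genotype, haploid_gt)

    def next_id(svtype: str) -> str:
        n = id_counter.get(svtype, 0) + 1
        id_counter[svtype] = n
        return f"{svtype}.{n}"

    def line(chrom, pos1, rid, ref, alt, info_pairs):
        info = _info_str(info_pairs)
        return (chrom, pos1, rid,
                f"{chrom}\t{pos1}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gt}")

    if c.sv_type == "BND":
        adj = c.adjacency
        n = id_counter.get("BND", 0)
        id_counter["BND"] = n + 2
        id1, id2 = f"BND.{n + 1}", f"BND.{n + 2}"
        base1 = reference.fetch(adj.chrom1, adj.pos1, adj.pos1 + 1)
        base2 = reference.fetch(adj.chrom2, adj.pos2, adj.pos2 + 1)
        alt1 = _bnd_alt(base1, adj.dir1, adj.chrom2, adj.pos2 + 1, adj.dir2)
        alt2 = _bnd_alt(base2, adj.dir2, adj.chrom1, adj.pos1 + 1, adj.dir1)
        return [
            line(adj.chrom1, adj.pos1 + 1, id1, base1, alt1, [("SVTYPE", "BND"), ("MATEID", id2)]),
            line(adj.chrom2, adj.pos2 + 1, id2, base2, alt2, [("SVTYPE", "BND"), ("MATEID", id1)]),
        ]

    if c.end > reference.length(c.ref_name) or c.start < 0:
        raise ValueError(f"candidate {c.sv_type} at {c.ref_name}:{c.start} outside reference")

    if c.sv_type == "DEL":
        rid = next_id("DEL")
        info = [("SVTYPE", "DEL"), ("END", c.end), ("SVLEN", -c.sv_length)]
        if c.start == 0:
            # no base to the left: pad with the base following the deleted span
            ref_allele = reference.fetch(c.ref_name, 0, c.end + 1)
            alt_allele = ref_allele[-1]
            return [line(c.ref_name, 1, rid, ref_allele, alt_allele, info)]
        pad = reference.fetch(c.ref_name, c.start - 1, c.start)
        if c.sv_length > symbolic_del_threshold:
            return [line(c.ref_name, c.start, rid, pad, "<DEL>", info)]
        ref_allele = reference.fetch(c.ref_name, c.start - 1, c.end)
        return [line(c.ref_name, c.start, rid, ref_allele, pad, info)]

    if c.sv_type == "INS":
        rid = next_id("INS")
        pad_pos = max(c.start - 1, 0)
        pad = reference.fetch(c.ref_name, pad_pos, pad_pos + 1)
        info = [("SVTYPE", "INS"), ("SVLEN", c.sv_length)]
        alt = pad + c.alt_sequence if c.alt_sequence else "<INS>"
        return [line(c.ref_name, pad_pos + 1, rid, pad, alt, info)]

    if c.sv_type in ("INV", "DUP_TANDEM"):
        svtype = "INV" if c.sv_type == "INV" else "DUP:TANDEM"
        rid = next_id(svtype)
        pad_pos = max(c.start - 1, 0)
        pad = reference.fetch(c.ref_name, pad_pos, pad_pos + 1)
        info = [("SVTYPE", svtype), ("END", c.end), ("SVLEN", c.sv_length)]
        return [line(c.ref_name, pad_pos + 1, rid, pad, f"<{svtype}>", info)]

    if c.sv_type == "DUP_INT":
        rid = next_id("DUP:INT")
        pad_pos = max(c.start - 1, 0)
        pad = reference.fetch(c.ref_name, pad_pos, pad_pos + 1)
        src_chrom, src_start, src_end = c.source_interval
        info = [
            ("SVTYPE", "DUP:INT"),
            ("END", pad_pos + 1),
            ("SVLEN", c.sv_length),
            ("SOURCE", f"{src_chrom}:{src_start + 1}-{src_end}"),
        ]
        return [line(c.ref_name, pad_pos + 1, rid, pad, "<DUP:INT>", info)]

    raise ValueError(f"unknown SV type {c.sv_type!r}")


def write_vcf(
    candidates: Iterable[SvCandidate],
    reference,
    sample_name: str,
    out,
    haploid_gt: str = "./1",
    symbolic_del_threshold: int = 10_000,
    command_line: Optional[str] = None,
    extra_header_lines: Optional[Sequence[str]] = None,
    file_date: Optional[str] = None,
) -> None:
    """Write a sorted VCF for the given candidates.

    Records are sorted by (contig header order, POS, ID); IDs are ordinal per
    SVTYPE. ``reference`` may be a FASTA path, a ``pysam.FastaFile`` or a
    name→sequence mapping (contig header order follows its order).
    """
    reference = Reference(reference)
    names = reference.names
    contig_rank = {name: i for i, name in enumerate(names)}

    header: List[str] = ["##fileformat=VCFv4.2"]
    header.append(f"##fileDate={file_date or datetime.date.today().strftime('%Y%m%d')}")
    header.append("##source=asmsv")
    if command_line:
        header.append(f"##commandline={command_line}")
    if extra_header_lines:
        header.extend(extra_header_lines)
    for name in names:
        header.append(f"##contig=<ID={name},length={reference.length(name)}>")
    header.extend(_HEADER_DEFINITIONS)
    header.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}")

    ordered = sorted(
        candidates, key=lambda c: (contig_rank.get(c.ref_name, len(names)), c.start, c.sv_type)
    )
    id_counter: dict = {}
    records: List[Tuple[int, int, str, str]] = []
    for cand in ordered:
        for chrom, pos1, rid, text in format_record(
            cand, reference, id_counter, haploid_gt, symbolic_del_threshold
        ):
            records.append((contig_rank[chrom], pos1, rid, text))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    with open(out, "w") as handle:
        for entry in header:
            handle.write(entry + "\n")
        for _, _, _, text in records:
            handle.write(text + "\n")
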