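# Methods

This note documents the model behind `asmsv`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Input model

The caller consumes contig-to-reference alignments, not reads. Assembly
alignments differ from read alignments in ways that shape the design: there
are few records, each very long and of high quality; coverage of each locus
by one haplotype is ~1×, so a single discordant alignment is treated as
sufficient evidence (there is no read-support counting); and split contigs
are represented as one primary plus hard-clipped supplementary records, so
clip lengths must be trusted to recover full-contig coordinates
(`alignment_io.query_interval_on_forward_strand`). Soft and hard clips are
treated identically; secondary alignments are always discarded. No
mapping-quality or length filter is applied by default (`--min-mapq 0`) —
assembly alignments are few and pre-filtered by the aligner, and the flag
is there for users who disagree.

All coordinates are 0-based half-open internally; the only 1-based
conversion happens in the VCF writer. This removes a whole class of
off-by-one ambiguity between the modules.

## Signature extraction (COLLECT)

Intra-alignment evidence is read directly off the CIGAR: `I`/`D` operations
≥ `min_sv_size` become insertion/deletion signatures. Insertions are
anchored at the reference position where they interrupt the alignment
(`start == end == anchor`), which maps 1:1 onto VCF padding-base semantics.
Nearby sub-threshold gaps are *not* merged into larger events: assembly
aligners already consolidate alignments, and merging would add a heuristic
with no principled threshold.

Inter-alignment evidence compares consecutive segments of one contig in
forward-contig order. With query gap `q = b.query_start − a.query_end` and
reference gap `r` (strand-aware), the classification is:

| geometry | call |
|---|---|
| `min_sv_size ≤ r ≤ max_sv_size`, `q ≤ query_gap_tolerance` | DEL over the skipped span |
| `q ≥ min_sv_size`, `abs(r) ≤ reference_gap_tolerance` | INS at the junction |
| both `r` and `q` ≥ `min_sv_size` | replacement → DEL + INS (the six output classes have no "replacement" type) |
| `r ≤ −min_sv_size`, `q ≤ query_gap_tolerance` | DUP_TANDEM over the twice-covered span |
| opposite strands or `abs(r) > max_sv_size` or different chromosomes | reciprocal BND pair |

Small query overlaps (`−query_gap_tolerance ≤ q < 0`), as produced by
aligner overlap artifacts, are clamped to zero rather than split at a
midpoint: a true midpoint convention would require re-walking both CIGARs
to map query to reference inside the segments, for a breakpoint shift
bounded by the tolerance itself. Larger overlaps void the pair.

Three-segment windows (A, B, C) detect the classes that need a middle
segment: an opposite-strand B that fills the reference gap between
collinear A and C is an inversion over B's reference interval; a B mapping
to a distant locus between *tightly* collinear A and C (`|C.ref_start −
A.ref_end| ≤ reference_gap_tolerance` — an inserted copy consumes no
reference) is an interspersed duplication with B's interval as the source
and `A.ref_end` as the insertion anchor. Pairs consumed by a triple are
excluded from pairwise breakend output; an orientation switch that no
triple explains (e.g. an inversion breakpoint at a contig end) degrades to
a reciprocal BND pair — the lossless representation — rather than a
partial inversion call.

Breakend orientation bookkeeping: each adjacency stores, per endpoint,
which *side* of the breakend base joins (`right` for `t[`/`t]` records,
`left` for `]p]t`/`[p[t`), covering the four canonical bracket
combinations. The two reciprocal signature mates are collapsed to one
canonically ordered record during within-haplotype deduplication, so each
adjacency is exactly one candidate and two VCF lines.

## Pairing and genotyping (PAIR, GENOTYPE)

"Haplotype sequence" is interpreted as the variant's own sequence: the
inserted bases for insertions and interspersed duplications. Their
normalized distance is `edit_distance(s1, s2) / max(len1, len2)` (edlib,
unit costs). Deletion-type signatures (DEL/INV/DUP_TANDEM) carry no variant
sequence, and fetching reference context would add I/O for little benefit
at assembly quality; the relative length difference
`|len1 − len2| / max(len1, len2)` substitutes. Breakends pair when both
endpoints agree within `pairing_max_span_distance` and orientations match.
Two empty/zero-length sequences are at distance 0 by definition.

Defaults: `pairing_max_span_distance = 1000` bp,
`pairing_max_edit_fraction = 0.3` — permissive enough for legitimate
allele differences between haplotypes (at 0.5% divergence two alleles of a
5 kb insertion differ by ~1% of their length, far below 0.3), strict
enough that unrelated random sequences (expected normalized distance
≈ 0.5) never merge. Both are flags.

Matching across haplotypes is greedy by ascending distance, with ties
broken by reference position and then input order — fully deterministic,
and at the few-signatures-per-locus density of assemblies it attains the
maximum matching (the test suite verifies this against brute-force
enumeration on small conflict sets). An optimal assignment solver would add
complexity with no observable effect. Merged (homozygous) candidates take
their coordinates from the haplotype-1 representative: the two alleles may
legitimately differ slightly, and a deterministic choice beats averaging.

Within one haplotype, signatures reported twice by overlapping contigs are
deduplicated with the same similarity test; the representative is the
signature with the longest supporting alignment (ties: leftmost).

## VCF output

VCF 4.2. Deletions and insertions are sequence-resolved (padding base +
run of deleted/inserted bases) so that sequence-aware benchmarkers can
compare alleles; deletions above `--symbolic-del-threshold` (default
10 kb) fall back to symbolic `<DEL>` to bound file size. Inversions and
duplications are symbolic; the interspersed-duplication record sits at the
insertion anchor with the source locus in `INFO/SOURCE`, keeping one
record per event. `SVLEN` is negative for deletions, positive otherwise;
`END` is omitted for insertions and breakends. Haploid calls are written
as `./1`: presence is known but zygosity is not estimable from a single
haplotype (flag-controlled for users who prefer `1/1`). Records are sorted
by (contig header order, POS, ID); IDs are ordinal per SVTYPE; the
parameter set is echoed into the header for provenance.

## Synthetic benchmark

`synthetic_genome` builds the study conditions used by the tests and the
acceptance script: a uniform-composition random reference of 2 × 250 kb,
implanted with 30 DEL, 30 INS, 6 INV, 6 DUP_TANDEM, 4 DUP_INT and 4
inter-chromosomal adjacencies, sizes drawn log-uniformly from 50–5000 bp
(log-uniform mirrors the heavy skew of real SV size distributions),
homozygous with probability 0.5, heterozygous events assigned to a uniform
haplotype. Events are placed with a 750 bp guard zone, so distinct events
are > 1500 bp apart — more than `pairing_max_span_distance`, which makes
cross-pairing of *different* events geometrically impossible and keeps the
fixture's genotype truth unambiguous. Breakends are realized as fusion
contigs joining 2 kb flanks of the two endpoints (drawn in all four
orientation combinations); the other classes are implanted into the linear
haplotype sequences.

Alignments are constructed analytically from the implant arithmetic:
`gapped` style encodes DEL/INS as CIGAR operations inside one record,
`split` style breaks records at every breakpoint; inversions, duplications
and fusions always split, since no single gapped record can express them.
Primary records are soft-clipped with the full contig sequence,
supplementaries hard-clipped — the shape minimap2 produces. An optional
divergence rate adds independent point mutations to each haplotype
(rate/2 each, so the expected *pairwise* divergence matches the nominal
rate); the acceptance run uses 0.5%, the value typical of human
haplotype pairs.

The evaluator is a deliberately simple truvari-like matcher: greedy
one-to-one matching requiring the same class, position within 10 bp,
length within 30%, breakends by adjacency endpoints and orientations. It
does not score sequence similarity — sufficient for noise-free fixtures
with guard-separated events, and dependency-free. Metrics with zero
denominators are reported as 0 and flagged.

What passing on this fixture shows: the coordinate bookkeeping (CIGAR,
clips, strands, split geometries, 1-based conversion), the classification
rules, the pairing/genotyping logic and the VCF round trip are exact. What
it does not show: robustness to assembly errors, repeat-mediated or nested
SVs, imprecise aligner breakpoints, or reference bias — real-data behavior
depends on the upstream assembly and alignment quality in ways no
synthetic fixture certifies.

## Problem sizes and numerics

The default fixture (500 kb genome, 80 SVs) runs the full pipeline in a
few seconds; the deduplication and matching steps are quadratic per locus
group but signature counts per locus are tiny in assembly data. Edit
distances are exact (no banding). All randomness flows through explicit
seeds (`numpy.random.default_rng`); the caller itself is deterministic,
and repeated runs produce byte-identical VCFs apart from the `##fileDate`
header line.

## Known limitations

* Balanced/cut-and-paste translocations are reported only as their
  breakend pairs, not reconstructed as events.
* Nested and complex SVs are out of scope; overlapping evidence produces
  the per-junction calls the geometry supports.
* Deletion-type pairing uses length similarity only, so two different
  same-length deletions closer than `pairing_max_span_distance` on
  opposite haplotypes would merge; at assembly SV densities this is rare.
* No CRAM or PAF input; no multi-sample merging or phasing (PS) output.
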