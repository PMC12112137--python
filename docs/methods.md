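# Methods

## The problem

In *Bacillus subtilis* an antisense RNA (ArrA) is transcribed from the
strand opposite the *dnaA* 5' leader, from a SigA-type promoter that sits
in the *rpmH*–*dnaA* intergenic region and is flanked by two DnaA binding
sites. The promoter's composition — a consensus −10 (TATAAT), a −35 with
two mismatches from TTGACA, a 16-bp spacer — and the exact gaps between
the −10 and the two boxes are conserved across part of the *Bacillus*
genus, in three discrete geometries. `arrascan` turns that comparative
observation into a deterministic, testable procedure: extract the
intergenic region on the antisense strand, scan it for promoter elements
and DnaA boxes, and classify the architecture by its gap pattern.

## Region extraction

The target region is everything strictly between the *rpmH* and *dnaA*
gene bodies, reported 5'→3' on the strand antisense to *dnaA* (reading
from the *dnaA*-proximal end toward *rpmH*). Internally all coordinates
are 0-based half-open; GenBank's 1-based inclusive convention exists only
at the parse/serialize boundary. "Gene body" means the annotated gene
feature, falling back to CDS when no gene features exist; gene matching is
case-insensitive on the symbol, with a fallback to product text
("DnaA" / "L34") because RefSeq symbol usage varies. Zero or multiple
matches for an anchor are per-locus errors (the pipeline records a skipped
row), never silent choices.

On a circular replicon there are two arcs between two non-overlapping
genes. For same-direction genes — the real *rpmH*–*dnaA* layout, with
*rpmH* immediately upstream of *dnaA* — the intergenic region is the arc
running from the upstream gene's end to the downstream gene's start in the
direction of transcription; it may wrap the origin (encoded as
`start > end`). For mixed orientations the shorter arc is used as a
fallback. Wrapping intervals are legal only on records declaring circular
topology. Every `TargetRegion` carries provenance (interval, strand,
genome length, circularity) sufficient to re-slice the genome and
reproduce the region byte-for-byte; that round trip is asserted in tests
for all strand/wrap combinations.

## Motif model

Matching is consensus-plus-Hamming throughout. A position counts as a
mismatch when the characters differ or either is `N`. No position weight
matrix is trained: the quantities the classification depends on are
*mismatch counts* against the canonical hexamers, and the DnaA-box
evidence in the source data supports a proportional similarity
(matches / width), so a PWM would add parameters without adding
information.

Scan parameters (`ScanParams`), with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `consensus_m10` | `TATAAT` | SigA −10 consensus |
| `consensus_m35` | `TTGACA` | SigA −35 consensus |
| `max_mm10` | 1 | loosest −10 among accepted candidates (e.g. TATAGT) |
| `max_mm35` | 2 | loosest −35 among accepted candidates (TACACA, ATGAAA) |
| `spacer_range` | 15–18 bp | brackets canonical SigA spacing; classification additionally demands exactly 16 |
| `box_consensus` | `TTATCCACA` | the *B. subtilis* 9-mer DnaA-box consensus; a documented, configurable stand-in |
| `min_box_matches` | 7 of 9 | similarity threshold for reporting a box |
| `tss_offset` | 7 nt | reporting convention for the predicted start site (3' end of the −10 + 7, inclusive); never enters classification |

The promoter scan runs only on the region's own strand (the promoter
sought is antisense to *dnaA*); the box scan runs on both orientations,
since DnaA boxes occur in either direction. Candidate ordering is
contractual: promoters sort by total mismatches, then |spacer − 16|, then
leftmost −10, then leftmost −35 (the last key makes the order total when
two spacers are equidistant from 16); boxes sort by start then
orientation. Both scanners are checked against independent brute-force
enumerations on every instance up to 2 kb used in the tests.

## Gap measurement and classification

Relative to an accepted promoter's −10 hexamer, the *upstream* box is the
best box on the −35 side whose near edge lies 0–12 nt from the −10; the
*downstream* box is the best box on the opposite side within 0–20 nt.
"Best" is highest similarity, ties broken toward the box nearest the −10,
then leftmost — a total order, so permuting the box list cannot change the
call. Box orientation is ignored for gap measurement: the conserved
quantity is spacing, not direction. The search windows are conventions
chosen to bound the search without excluding any defined group.

Groups are fixed by the exact pair (gap to downstream box, gap to
upstream box): I = (16, 2), II = (14, 4), III = (11, 7), all with spacer
exactly 16 bp. The first promoter in scan order with a 16-bp spacer and a
matching gap pair fixes the call; candidates present but no match →
`unclassified` (top candidate and best-effort gaps recorded); no
candidates at all → group IV. Matching is exact by default — a 2-bp shift
*is* a different group — with an optional `gap_tolerance` (default 0) for
exploration only. Every I/II/III call necessarily satisfies
`g_up + 6 + g_down = interbox_gap = 24`, and that conservation law is
asserted on all synthetic calls.

Tightening any budget can only shrink the candidate and hit sets, so calls
move monotonically toward IV/unclassified, never between I, II and III.

## Transcript arithmetic

Lengths are inclusive position counts: a run-off product spans the start
site through the template edge; a terminated product spans the start site
through the terminator's recorded last transcribed base (product sizes,
not 3'-end chemistry, define the coordinate). Terminators are enumerated
in order of distance; a readthrough-permissive terminator yields its
isoform and lets enumeration continue, the first hard terminator ends it,
and a run-off isoform is appended only when every terminator is
permissive. Whether a short in vivo species is a termination or a
processing product is deliberately not modelled — the readthrough flag is
the only representation. The module never infers genomic start sites; the
analysis layouts use synthetic coordinates constructed to the template
sizes the products were measured on.

## Synthetic loci

The generator emulates the one thing the pipeline consumes: an annotated
locus with two same-direction gene stubs (rpmH, 135 nt; dnaA, 99 nt)
flanking an intergenic region (default 300 nt) whose antisense strand
carries a planted architecture. For groups I–III it plants a consensus
−10, a −35 with exactly two seed-chosen substitutions at a 16-bp spacer,
and two exact consensus boxes at the group's gaps; for group IV, two boxes
24 bp apart and no promoter. Element positions are seed-jittered with
≥20-nt margins.

Background bases are i.i.d. at a configurable GC fraction (default 0.44,
near the *B. subtilis* genome average); no higher-order sequence model is
used because the scanner is consensus-based and insensitive to
dinucleotide structure. The background is accepted by rejection sampling:
a draw passes only when the default-parameter scans report exactly the
planted elements and nothing else. Rejection (bounded at 1,000 redraws,
loud failure reporting the seed) keeps the accepted background a cleanly
conditioned i.i.d. sample rather than a post-edited sequence. Typical
acceptance uses a handful of redraws at the default length.

Loci are wrapped into genomes on either strand, optionally rotated so the
intergenic region spans the origin of a circular record — exercising the
reverse-complement and origin-wrap extraction paths. Identical arguments
give byte-identical records; panel generation assigns per-locus seeds
`base_seed + index` and varies strand/wrap cyclically regardless of the
count mapping's insertion order.

What passing on synthetic loci does **not** show: real intergenic regions
have compositional structure, imperfect boxes, annotation noise, and
promoters that may only be recognizable after alignment-assisted visual
inspection. Recovery of planted architectures validates the machinery
(coordinates, orientation, gap arithmetic, determinism), not the
sensitivity of the consensus thresholds on real genomes — reproducing the
published cohort tallies on real RefSeq files additionally depends on the
exact genome set and on curation the original survey applied by eye.

## Anchor alignment

The displayed comparison of loci is an anchored, gapless alignment: rows
are left-padded so every call's downstream (conserved) DnaA box starts in
the same column, then right-padded to equal width. Classification never
depends on the alignment; a general-purpose MSA is out of scope, and rows
lacking an anchor box are excluded and logged.

## Determinism and problem sizes

Every stochastic step flows from an explicit seed through a single
`numpy` generator per locus; all orderings are total; data files carry no
timestamps, so repeated runs are byte-identical (asserted in tests). The
test suite and the acceptance script run on synthetic panels of 36–210
loci at 300-nt regions — sizes chosen because recovery there is already a
strict functional check while the whole suite stays fast enough to run on
every change; all scan algorithms are linear in region length and run
unchanged on multi-kilobase regions.

## Known limitations

- The DnaA-box consensus and threshold are explicit stand-ins; the
  original survey's exact box criterion is not machine-recoverable.
- Consensus/Hamming scoring has no notion of position-specific
  information; weak but real boxes below 7/9 are invisible.
- `unclassified` is a bucket, not a model: partial or shifted
  architectures are recorded with best-effort gaps but not scored.
- The extractor assumes exactly one locus per record (one *dnaA*, one
  *rpmH*); multi-copy or split annotations are reported as errors rather
  than resolved.
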