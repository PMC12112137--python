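"""Reading annotated genomes and extracting the rpmH–dnaA intergenic region.

The region of interest lies strictly between the *rpmH* and *dnaA* gene
bodies.  Because the antisense RNA promoter being sought reads against
*dnaA*, the extracted :class:`TargetRegion` sequence is always given 5'→3'
on the strand antisense to *dnaA*, starting from the *dnaA*-proximal end.
Provenance (source interval, source strand, genome length, circularity) is
retained so every region offset maps back to an exact genome coordinate.

Conventions
-----------
* Coordinates are 0-based half-open internally; GenBank 1-based inclusive
  appears only at the Biopython parse/serialize boundary.
* An origin-wrapping interval is encoded as ``start > end`` and is legal
  only on records declaring circular topology.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import (
    AmbiguousAnchorError,
    AnchorGeneError,
    FormatError,
    GeometryError,
    InputError,
)
from .sequences import circular_slice, interval_length, revcomp, validate_alphabet

# Product-text fallbacks when RefSeq records carry no usable gene symbol.
# rpmH encodes 50S ribosomal protein L34; dnaA the replication initiator.
_PRODUCT_FALLBACK = {"dnaa": ("dnaa",), "rpmh": ("l34", "ribosomal protein l34")}


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body on a genome: 0-based half-open, non-wrapping."""

    name: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene annotation requires a non-empty name")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomeRecord:
    identifier: str
    sequence: str
    circular: bool = False
    annotations: tuple[GeneAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        validate_alphabet(self.sequence, what=f"genome {self.identifier}")
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise ValueError(
                    f"annotation {ann.name} extends past genome end "
                    f"({ann.end} > {len(self.sequence)})"
                )


@dataclass(frozen=True)
class TargetRegion:
    """The intergenic sequence, 5'→3' on the strand antisense to dnaA.

    ``source_interval`` is 0-based half-open on the genome forward strand;
    ``start > end`` encodes an origin wrap.  ``source_strand`` is the genome
    strand the region string was read from: slicing the genome at
    ``source_interval`` and reverse-complementing when ``source_strand`` is
    ``-`` reproduces ``sequence`` exactly.
    """

    genome_id: str
    sequence: str
    source_interval: tuple[int, int]
    source_strand: str
    genome_length: int
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_genome_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a region-frame half-open interval to genome coordinates.

        The returned interval is half-open on the genome forward strand and
        may wrap (start > end) on circular genomes.
        """
        if not 0 <= start <= end <= self.length:
            raise ValueError(f"region interval ({start}, {end}) out of bounds")
        n = self.genome_length
        s0, _e0 = self.source_interval
        if self.source_strand == "+":
            g_start = (s0 + start) % n
            g_end = (s0 + end) % n
        else:
            # region offset 0 sits at the last base of the source interval
            e_excl = (s0 + self.length) % n  # exclusive end of source slice
            g_start = (e_excl - end) % n
            g_end = (e_excl - start) % n
        if start == end:
            g_end = g_start
        return g_start, g_end


def _name_from_qualifiers(quals: dict) -> tuple[str, str]:
    name = ""
    for key in ("gene", "locus_tag"):
        if quals.get(key):
            name = quals[key][0]
            break
    product = quals.get("product", [""])[0]
    return name, product


def _annotations_from_features(features) -> tuple[GeneAnnotation, ...]:
    """Harvest gene annotations, preferring ``gene`` features over CDS."""
    collected: list[GeneAnnotation] = []
    seen_spans: set[tuple[int, int]] = set()
    for wanted in ("gene", "CDS"):
        for feat in features:
            if feat.type != wanted:
                continue
            loc = feat.location
            if loc is None:
                continue
            start, end = int(loc.start), int(loc.end)
            if (start, end) in seen_spans:
                continue
            name, product = _name_from_qualifiers(feat.qualifiers)
            if not name and not product:
                continue
            strand = "-" if loc.strand == -1 else "+"
            collected.append(
                GeneAnnotation(name or f"feature_{start}_{end}", start, end, strand, product)
            )
            seen_spans.add((start, end))
    collected.sort(key=lambda a: (a.start, a.end, a.name))
    return tuple(collected)


def _record_from_seqrecord(rec: SeqRecord) -> GenomeRecord:
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError(f"record {rec.id!r} carries no sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    return GenomeRecord(
        identifier=rec.id,
        sequence=seq,
        circular=circular,
        annotations=_annotations_from_features(rec.features),
    )


def _read_genbank(path: Path) -> list[GenomeRecord]:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    return [_record_from_seqrecord(r) for r in records]


def _read_fasta_gff3(fasta_path: Path, gff_path: Path) -> list[GenomeRecord]:
    import gffutils

    try:
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:
        raise FormatError(f"{fasta_path}: not parseable as FASTA: {exc}") from exc
    if not seqs:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"{gff_path}: not parseable as GFF3: {exc}") from exc

    per_seq_features: dict[str, list] = {sid: [] for sid in seqs}
    circular: dict[str, bool] = {sid: False for sid in seqs}
    for feat in db.all_features():
        if feat.seqid not in seqs:
            continue
        if feat.featuretype == "region":
            flag = feat.attributes.get("Is_circular", ["false"])[0]
            circular[feat.seqid] = str(flag).lower() == "true"
            continue
        if feat.featuretype not in ("gene", "CDS"):
            continue
        per_seq_features[feat.seqid].append(feat)

    records = []
    for sid, seq in seqs.items():
        anns: list[GeneAnnotation] = []
        seen: set[tuple[int, int]] = set()
        for wanted in ("gene", "CDS"):
            for feat in per_seq_features[sid]:
                if feat.featuretype != wanted:
                    continue
                start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
                if (start, end) in seen:
                    continue
                name = ""
                for key in ("gene", "Name", "locus_tag"):
                    if key in feat.attributes:
                        name = feat.attributes[key][0]
                        break
                product = feat.attributes.get("product", [""])[0]
                if not name and not product:
                    continue
                strand = "-" if feat.strand == "-" else "+"
                anns.append(GeneAnnotation(name or f"feature_{start}_{end}",
                                           start, end, strand, product))
                seen.add((start, end))
        anns.sort(key=lambda a: (a.start, a.end, a.name))
        records.append(GenomeRecord(sid, seq, circular[sid], tuple(anns)))
    return records


def _resolve_gff(path: Path, gff_path) -> Path:
    if gff_path is not None:
        return Path(gff_path)
    for suffix in (".gff3", ".gff"):
        candidate = path.with_suffix(suffix)
        if candidate.exists():
            return candidate
    raise InputError(f"no GFF3 companion found for {path}")


def read_genomes(path, format: str = "genbank", gff_path=None) -> list[GenomeRecord]:
    """Read all records from an annotated genome file.

    ``format`` is ``"genbank"`` or ``"fasta+gff3"``; in the latter case
    ``path`` names the FASTA and ``gff_path`` the GFF3 (default: ``path``
    with a ``.gff3``/``.gff`` suffix).
    """
    path = Path(path)
    if not path.exists() or not os.access(path, os.R_OK):
        raise InputError(f"cannot read input file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: file is empty")
    if format == "genbank":
        return _read_genbank(path)
    if format in ("fasta+gff3", "fasta-gff"):
        return _read_fasta_gff3(path, _resolve_gff(path, gff_path))
    raise ValueError(f"unknown format {format!r}; use 'genbank' or 'fasta+gff3'")


def read_genome(path, format: str = "genbank", gff_path=None) -> GenomeRecord:
    """Read a single-record genome file (error if the file holds several)."""
    records = read_genomes(path, format=format, gff_path=gff_path)
    if len(records) != 1:
        raise FormatError(
            f"{path}: expected exactly one record, found {len(records)}; "
            "use read_genomes for multi-record files"
        )
    return records[0]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _match_annotations(genome: GenomeRecord, symbol: str) -> list[GeneAnnotation]:
    sym = symbol.lower()
    hits = [a for a in genome.annotations if a.name.lower() == sym]
    if hits:
        return hits
    needles = _PRODUCT_FALLBACK.get(sym, (sym,))
    return [
        a for a in genome.annotations
        if a.product and any(n in a.product.lower() for n in needles)
    ]


def _find_unique(genome: GenomeRecord, symbol: str) -> GeneAnnotation:
    hits = _match_annotations(genome, symbol)
    if not hits:
        raise AnchorGeneError(
            f"anchor gene absent: no annotation matching {symbol!r} "
            f"in {genome.identifier}"
        )
    if len(hits) > 1:
        coords = ", ".join(f"[{a.start},{a.end},{a.strand}]" for a in hits)
        raise AmbiguousAnchorError(
            f"{symbol!r} matches {len(hits)} annotations in "
            f"{genome.identifier}: {coords}"
        )
    return hits[0]


def _intergenic_interval(
    genome: GenomeRecord, a: GeneAnnotation, b: GeneAnnotation
) -> tuple[int, int]:
    """Half-open interval strictly between the two gene bodies.

    On a linear genome the between-interval is unique.  On a circular
    genome there are two arcs; for same-direction genes (the rpmH–dnaA
    layout, with rpmH transcribed immediately upstream of dnaA) the
    intergenic region is the arc running from the upstream gene's end to
    the downstream gene's start in the direction of transcription.  For
    mixed-orientation genes the shorter arc is taken as a fallback.
    """
    if a.start < b.end and b.start < a.end:
        raise GeometryError(
            f"{a.name} [{a.start},{a.end}) overlaps {b.name} [{b.start},{b.end})"
        )
    if not genome.circular:
        if a.end <= b.start:
            return a.end, b.start
        return b.end, a.start
    n = len(genome.sequence)
    if a.strand == b.strand:
        # rpmH (b) lies upstream of dnaA (a) in transcription direction
        if a.strand == "+":
            return b.end % n, a.start
        return a.end % n, b.start
    len_ab = interval_length(a.end % n, b.start, n)  # arc a -> b
    len_ba = interval_length(b.end % n, a.start, n)  # arc b -> a
    if len_ba <= len_ab:
        return b.end % n, a.start
    return a.end % n, b.start


def extract_target_region(
    genome: GenomeRecord, gene_a: str = "dnaA", gene_b: str = "rpmH"
) -> TargetRegion:
    """Extract the intergenic region between ``gene_a`` (dnaA) and ``gene_b``
    (rpmH), re-oriented 5'→3' on the strand antisense to ``gene_a``.

    When dnaA is annotated on the genome forward strand the region is the
    reverse complement of the forward slice (so it reads from the
    dnaA-proximal end toward rpmH); when dnaA is on the reverse strand the
    forward slice is already the antisense strand and is taken as is.
    """
    dnaa = _find_unique(genome, gene_a)
    rpmh = _find_unique(genome, gene_b)
    start, end = _intergenic_interval(genome, dnaa, rpmh)
    raw = circular_slice(genome.sequence, start, end)
    if dnaa.strand == "+":
        seq = revcomp(raw)
        source_strand = "-"
    else:
        seq = raw
        source_strand = "+"
    return TargetRegion(
        genome_id=genome.identifier,
        sequence=seq,
        source_interval=(start, end),
        source_strand=source_strand,
        genome_length=len(genome.sequence),
        circular=genome.circular,
    )


def reslice_region(genome: GenomeRecord, region: TargetRegion) -> str:
    """Re-derive a region sequence from its provenance (round-trip check)."""
    raw = circular_slice(genome.sequence, *region.source_interval)
    return revcomp(raw) if region.source_strand == "-" else raw


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_seqrecord(genome: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description="synthetic rpmH-dnaA locus" if "synthetic" in genome.identifier
        else "",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    for ann in genome.annotations:
        strand = -1 if ann.strand == "-" else 1
        quals = {"gene": [ann.name]}
        if ann.product:
            quals["product"] = [ann.product]
        rec.features.append(
            SeqFeature(FeatureLocation(ann.start, ann.end, strand), type="gene",
                       qualifiers=quals)
        )
    return rec


def write_genbank(genomes: GenomeRecord | Iterable[GenomeRecord], path) -> None:
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    SeqIO.write([to_seqrecord(g) for g in genomes], str(path), "genbank")


def write_fasta_gff3(genome: GenomeRecord, fasta_path, gff_path) -> None:
    SeqIO.write(
        SeqRecord(Seq(genome.sequence), id=genome.identifier, description=""),
        str(fasta_path),
        "fasta",
    )
    n = len(genome.sequence)
    lines = ["##gff-version 3", f"##sequence-region {genome.identifier} 1 {n}"]
    circ = "true" if genome.circular else "false"
    lines.append(
        f"{genome.identifier}\tarrascan\tregion\t1\t{n}\t.\t+\t.\t"
        f"ID=region0;Is_circular={circ}"
    )
    for i, ann in enumerate(genome.annotations):
        attrs = f"ID=gene{i};gene={ann.name}"
        if ann.product:
            attrs += f";product={ann.product}"
        lines.append(
            f"{genome.identifier}\tarrascan\tgene\t{ann.start + 1}\t{ann.end}\t.\t"
            f"{ann.strand}\t.\t{attrs}"
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")


def region_fasta_entry(region: TargetRegion) -> str:
    """FASTA entry for an extracted region: header genome_id|interval|strand."""
    s, e = region.source_interval
    header = f"{region.genome_id}|{s}-{e}|{region.source_strand}"
    return f">{header}\n{region.sequence}\n"


def write_regions_fasta(regions: Sequence[TargetRegion], path) -> None:
    Path(path).write_text("".join(region_fasta_entry(r) for r in regions))


def bed_line(
    chrom: str, start: int, end: int, name: str, score: int, strand: str
) -> str:
    return f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}"
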