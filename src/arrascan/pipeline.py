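"""Orchestration: extraction → box scan → promoter scan → classification,
plus table/BED/FASTA emission and the anchor alignment.

A run is deterministic for fixed inputs and configuration: rows are sorted,
data files carry no timestamps, and all tie-breaks downstream are total
orders.  Per-locus anchor problems (missing/ambiguous genes, bad geometry)
become ``skipped`` rows; only a complete absence of parseable input is
fatal.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .architecture import ArchitectureCall, classify_locus
from .errors import (
    AmbiguousAnchorError,
    AnchorGeneError,
    ArrascanError,
    FormatError,
    GeometryError,
    InputError,
)
from .genome_io import (
    GenomeRecord,
    TargetRegion,
    bed_line,
    extract_target_region,
    read_genomes,
    write_regions_fasta,
)
from .motifs import ScanParams, find_dnaa_boxes, scan_promoters

logger = logging.getLogger("arrascan")

_CALL_COLUMNS = [
    "genome_id", "status", "group",
    "m10_start", "m10_seq", "mm10",
    "m35_start", "m35_seq", "mm35",
    "spacer", "predicted_tss",
    "up_box_start", "up_box_seq", "up_box_matches",
    "down_box_start", "down_box_seq", "down_box_matches",
    "g_up", "g_down", "interbox_gap",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: tuple[str, ...] = ()
    format: str = "genbank"
    out_dir: Optional[str] = None
    params: ScanParams = field(default_factory=ScanParams)
    gap_tolerance: int = 0
    align: bool = True
    seed: int = 0


@dataclass(frozen=True)
class LocusResult:
    genome_id: str
    status: str  # "ok" or "skipped: <reason>"
    region: Optional[TargetRegion] = None
    call: Optional[ArchitectureCall] = None


@dataclass(frozen=True)
class AlignedBlock:
    """Rows left-padded so every anchor (downstream) box starts in the same
    column; all rows share one length."""

    rows: tuple[tuple[str, str], ...]
    anchor_column: int

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must share one length")


def analyze_region(
    region: TargetRegion, params: ScanParams | None = None, gap_tolerance: int = 0
) -> ArchitectureCall:
    """Scan one extracted region and classify its architecture."""
    params = params or ScanParams()
    boxes = find_dnaa_boxes(region, params)
    promoters = scan_promoters(region, params)
    return classify_locus(
        promoters, boxes, genome_id=region.genome_id, gap_tolerance=gap_tolerance
    )


def scan_records(
    records: Iterable[GenomeRecord],
    params: ScanParams | None = None,
    gap_tolerance: int = 0,
) -> list[LocusResult]:
    """Run the full per-locus analysis over in-memory genome records."""
    params = params or ScanParams()
    results: list[LocusResult] = []
    for genome in records:
        try:
            region = extract_target_region(genome)
        except (AnchorGeneError, AmbiguousAnchorError, GeometryError) as exc:
            logger.warning("skipping %s: %s", genome.identifier, exc)
            results.append(
                LocusResult(genome.identifier, f"skipped: {exc}")
            )
            continue
        call = analyze_region(region, params, gap_tolerance)
        results.append(LocusResult(genome.identifier, "ok", region, call))
    return results


def calls_table(results: Sequence[LocusResult]) -> pd.DataFrame:
    """One row per locus; region-frame element coordinates."""
    rows = []
    for res in results:
        row = dict.fromkeys(_CALL_COLUMNS)
        row["genome_id"] = res.genome_id
        row["status"] = res.status
        call = res.call
        if call is not None:
            row["group"] = call.group
            p = call.promoter
            if p is not None:
                row.update(
                    m10_start=p.m10_start, m10_seq=p.m10_seq, mm10=p.mm10,
                    m35_start=p.m35_start, m35_seq=p.m35_seq, mm35=p.mm35,
                    spacer=p.spacer, predicted_tss=p.predicted_tss,
                )
            if call.upstream_box is not None:
                row.update(
                    up_box_start=call.upstream_box.start,
                    up_box_seq=call.upstream_box.seq,
                    up_box_matches=call.upstream_box.matches,
                )
            if call.downstream_box is not None:
                row.update(
                    down_box_start=call.downstream_box.start,
                    down_box_seq=call.downstream_box.seq,
                    down_box_matches=call.downstream_box.matches,
                )
            row.update(g_up=call.g_up, g_down=call.g_down,
                       interbox_gap=call.interbox_gap)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    return frame.sort_values("genome_id", kind="stable").reset_index(drop=True)


def summary_table(results: Sequence[LocusResult]) -> pd.DataFrame:
    """Group tally over successfully analyzed loci, plus a skipped count."""
    counts: dict[str, int] = {}
    skipped = 0
    for res in results:
        if res.call is None:
            skipped += 1
        else:
            counts[res.call.group] = counts.get(res.call.group, 0) + 1
    order = ["I", "II", "III", "IV", "unclassified"]
    rows = [{"group": g, "count": counts.get(g, 0)} for g in order]
    rows.append({"group": "skipped", "count": skipped})
    return pd.DataFrame(rows)


def _element_bed_lines(res: LocusResult) -> list[str]:
    """Element intervals mapped back to genome coordinates, 6-column BED.

    Elements sit on the region's own strand (promoter) or carry their own
    orientation relative to it (boxes); the emitted strand is the genome
    strand of the element.  Origin-wrapping intervals are split into two
    lines.
    """
    region, call = res.region, res.call
    if region is None or call is None:
        return []

    def flip(s: str) -> str:
        return "-" if s == "+" else "+"

    items: list[tuple[int, int, str, int, str]] = []
    if call.promoter is not None:
        p = call.promoter
        items.append((p.m10_start, p.m10_start + 6, "minus10", 6 - p.mm10,
                      region.source_strand))
        items.append((p.m35_start, p.m35_start + 6, "minus35", 6 - p.mm35,
                      region.source_strand))
    for label, box in (("dnaA_box_up", call.upstream_box),
                       ("dnaA_box_down", call.downstream_box)):
        if box is not None:
            strand = region.source_strand if box.orientation == "+" \
                else flip(region.source_strand)
            items.append((box.start, box.end, label, box.matches, strand))

    lines = []
    for start, end, name, score, strand in items:
        g_start, g_end = region.to_genome_interval(start, end)
        if g_start <= g_end:
            lines.append(bed_line(region.genome_id, g_start, g_end, name,
                                  score, strand))
        else:  # wraps the origin: split
            n = region.genome_length
            lines.append(bed_line(region.genome_id, g_start, n,
                                  f"{name}_part1", score, strand))
            lines.append(bed_line(region.genome_id, 0, g_end,
                                  f"{name}_part2", score, strand))
    return lines


def elements_bed(results: Sequence[LocusResult]) -> str:
    lines: list[str] = []
    for res in sorted(results, key=lambda r: r.genome_id):
        lines.extend(_element_bed_lines(res))
    return "\n".join(lines) + ("\n" if lines else "")


def anchor_align(
    regions: Sequence[TargetRegion], calls: Sequence[ArchitectureCall]
) -> AlignedBlock:
    """Align regions on the conserved downstream DnaA box.

    Rows are shifted (left-padded with ``-``) so every anchor box starts in
    the same column, then right-padded to a common length.  Rows whose call
    lacks a downstream box are excluded and logged.
    """
    by_id = {c.genome_id: c for c in calls}
    keep: list[tuple[str, int, str]] = []
    for region in regions:
        call = by_id.get(region.genome_id)
        if call is None or call.downstream_box is None:
            logger.warning("anchor_align: excluding %s (no anchor box)",
                           region.genome_id)
            continue
        keep.append((region.genome_id, call.downstream_box.start, region.sequence))
    if not keep:
        logger.warning("anchor_align: no alignable rows")
        return AlignedBlock(rows=(), anchor_column=0)
    anchor_column = max(offset for _, offset, _ in keep)
    padded = [(gid, "-" * (anchor_column - offset) + seq)
              for gid, offset, seq in keep]
    width = max(len(s) for _, s in padded)
    rows = tuple((gid, s.ljust(width, "-")) for gid, s in padded)
    return AlignedBlock(rows=rows, anchor_column=anchor_column)


def aligned_block_fasta(block: AlignedBlock) -> str:
    return "".join(f">{gid}\n{row}\n" for gid, row in block.rows)


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig) -> list[GenomeRecord]:
    records: list[GenomeRecord] = []
    for path in config.inputs:
        try:
            records.extend(read_genomes(path, format=config.format))
        except (InputError, FormatError) as exc:
            logger.warning("unparseable input %s: %s", path, exc)
    return records


def scan_genomes(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-level run: read inputs, analyze every locus, write artifacts.

    Returns (calls table, summary table).  Raises InputError when no input
    parses at all.
    """
    records = _load_inputs(config)
    if not records:
        raise InputError(
            "no parseable inputs; point --input at GenBank or FASTA+GFF3 files"
        )
    results = scan_records(records, config.params, config.gap_tolerance)
    calls = calls_table(results)
    summary = summary_table(results)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "elements.bed").write_text(elements_bed(results))
        ok = [r for r in results if r.region is not None]
        write_regions_fasta([r.region for r in ok], out / "regions.fasta")
        if config.align:
            block = anchor_align(
                [r.region for r in ok],
                [r.call for r in ok if r.call is not None],
            )
            (out / "aligned.fasta").write_text(aligned_block_fasta(block))
    return calls, summary


def configure_logging(verbosity: int = 0) -> None:
    """Logs go to standard error; data outputs never mix with logs."""
    level = logging.WARNING if verbosity == 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
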