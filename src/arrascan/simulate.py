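"""Seeded generator of synthetic rpmH–dnaA loci with planted architectures.

Each locus is an annotated genome: an rpmH gene stub, an intergenic region,
and a dnaA gene stub, all same-direction.  The intergenic region's
antisense strand (the strand an antisense RNA of dnaA would be read from)
carries a planted promoter/box architecture:

* groups I/II/III — a consensus −10 (TATAAT), a −35 with exactly two
  seed-chosen mismatches from TTGACA at a 16-bp spacer, and two exact
  consensus DnaA boxes at the group's characteristic gaps;
* group IV — two consensus boxes 24 bp apart and no promoter.

Background bases are i.i.d. at a configurable GC fraction (default 0.44,
around the B. subtilis genome average).  The background is rejection
sampled: a draw is accepted only when the default-parameter scans report
exactly the planted elements and nothing else, so spurious hits cannot
arise by construction.  Rejection keeps the accepted background honestly
i.i.d.-conditioned rather than post-edited; failure after the redraw
budget raises, reporting the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ContractError, GenerationError
from .genome_io import GeneAnnotation, GenomeRecord, TargetRegion
from .motifs import SAME_STRAND, ScanParams, find_dnaa_boxes, scan_promoters
from .sequences import revcomp

#: (g_up, g_down) geometry planted per promoter-bearing group
PLANT_GEOMETRY = {"I": (2, 16), "II": (4, 14), "III": (7, 11)}

GROUP_ORDER = ("I", "II", "III", "IV")

_BASES = np.array(list("ACGT"))
_RPMH_LEN = 135
_DNAA_LEN = 99
_FLANK = 10
_MARGIN = 20


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated locus, in region (antisense-strand)
    offsets."""

    seed: int
    group: str
    region_length: int
    gc: float
    planted_m10_start: Optional[int]
    planted_m35_start: Optional[int]
    planted_box_starts: tuple[int, ...]
    genome_strand_of_dnaA: str
    circular_wrap: bool


def _draw_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return rng.choice(4, size=n, p=probs)


def _mutate_m35(rng: np.random.Generator, consensus: str) -> str:
    """Exactly two seed-chosen substitutions, each to a different base."""
    positions = sorted(rng.choice(len(consensus), size=2, replace=False))
    out = list(consensus)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _plant_layout(
    rng: np.random.Generator, group: str, region_length: int, params: ScanParams
):
    """Choose element offsets and sequences on the antisense region string."""
    box = params.box_consensus
    k = params.box_length
    if group in PLANT_GEOMETRY:
        g_up, g_down = PLANT_GEOMETRY[group]
        span = 6 + 16 + 6 + g_down + k  # −35 .. downstream box end
        if region_length < span + 2 * _MARGIN:
            raise ContractError(
                f"region_length {region_length} too short for group {group} "
                f"architecture plus margins (need ≥ {span + 2 * _MARGIN})"
            )
        m35_start = _MARGIN + int(rng.integers(region_length - span - 2 * _MARGIN + 1))
        m10_start = m35_start + 6 + 16
        up_start = m10_start - g_up - k
        down_start = m10_start + 6 + g_down
        m35_seq = _mutate_m35(rng, params.consensus_m35)
        elements = {
            m35_start: m35_seq,
            m10_start: params.consensus_m10,
            up_start: box,
            down_start: box,
        }
        return elements, m10_start, m35_start, (up_start, down_start)
    if group == "IV":
        span = k + 24 + k
        if region_length < span + 2 * _MARGIN:
            raise ContractError(
                f"region_length {region_length} too short for group IV boxes"
            )
        b1 = _MARGIN + int(rng.integers(region_length - span - 2 * _MARGIN + 1))
        b2 = b1 + k + 24
        return {b1: box, b2: box}, None, None, (b1, b2)
    raise ValueError(f"unknown group {group!r}; use one of {GROUP_ORDER}")


def _scan_matches_truth(
    region_seq: str,
    params: ScanParams,
    m10_start: Optional[int],
    m35_start: Optional[int],
    box_starts: tuple[int, ...],
) -> bool:
    """Accept a draw only if the scans see exactly the planted elements."""
    boxes = find_dnaa_boxes(region_seq, params)
    expected_boxes = [(s, SAME_STRAND) for s in sorted(box_starts)]
    if [(b.start, b.orientation) for b in boxes] != expected_boxes:
        return False
    if any(b.matches != params.box_length for b in boxes):
        return False
    promoters = scan_promoters(region_seq, params)
    if m10_start is None:
        return not promoters
    return len(promoters) == 1 and (
        promoters[0].m10_start,
        promoters[0].m35_start,
    ) == (m10_start, m35_start)


def generate_locus(
    group: str,
    seed: int,
    region_length: int = 300,
    gc: float = 0.44,
    strand: str = "+",
    circular_wrap: bool = False,
    params: ScanParams | None = None,
    max_redraws: int = 1000,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate one annotated synthetic locus with a planted architecture.

    ``strand`` is the genome strand carrying dnaA and rpmH;
    ``circular_wrap`` rotates a circular genome so the intergenic region
    spans the origin.  Identical arguments give byte-identical records.
    """
    if strand not in "+-":
        raise ContractError(f"strand must be '+' or '-', got {strand!r}")
    params = params or ScanParams()
    rng = np.random.default_rng(seed)
    elements, m10_start, m35_start, box_starts = _plant_layout(
        rng, group, region_length, params
    )

    region_seq = None
    for _ in range(max_redraws):
        codes = _draw_background(rng, region_length, gc)
        chars = _BASES[codes]
        for offset, motif in elements.items():
            chars[offset : offset + len(motif)] = list(motif)
        candidate = "".join(chars)
        if _scan_matches_truth(candidate, params, m10_start, m35_start, box_starts):
            region_seq = candidate
            break
    if region_seq is None:
        raise GenerationError(
            f"no spurious-hit-free background within {max_redraws} redraws "
            f"(group={group}, seed={seed}, region_length={region_length}, gc={gc})"
        )

    # gene stubs; their content never enters any scan
    rpmh_seq = "".join(_BASES[_draw_background(rng, _RPMH_LEN, gc)])
    dnaa_seq = "".join(_BASES[_draw_background(rng, _DNAA_LEN, gc)])
    flank5 = "".join(_BASES[_draw_background(rng, _FLANK, gc)])
    flank3 = "".join(_BASES[_draw_background(rng, _FLANK, gc)])

    # forward construction: rpmH .. revcomp(region) .. dnaA, genes on '+';
    # the antisense strand of the intergenic then reads the region 5'→3'
    # from the dnaA-proximal end, as extraction defines it.
    genome_seq = flank5 + rpmh_seq + revcomp(region_seq) + dnaa_seq + flank3
    rpmh_iv = (_FLANK, _FLANK + _RPMH_LEN)
    dnaa_iv = (_FLANK + _RPMH_LEN + region_length,
               _FLANK + _RPMH_LEN + region_length + _DNAA_LEN)

    if strand == "-":
        n = len(genome_seq)
        genome_seq = revcomp(genome_seq)
        rpmh_iv = (n - rpmh_iv[1], n - rpmh_iv[0])
        dnaa_iv = (n - dnaa_iv[1], n - dnaa_iv[0])

    annotations = [
        GeneAnnotation("rpmH", *rpmh_iv, strand, product="50S ribosomal protein L34"),
        GeneAnnotation("dnaA", *dnaa_iv, strand,
                       product="chromosomal replication initiator protein DnaA"),
    ]

    circular = circular_wrap
    if circular_wrap:
        # rotate so the origin falls mid-intergenic; genes stay contiguous
        n = len(genome_seq)
        inter_lo = min(rpmh_iv[1], dnaa_iv[1])
        rotation = (inter_lo + region_length // 2) % n
        genome_seq = genome_seq[rotation:] + genome_seq[:rotation]
        annotations = [
            GeneAnnotation(a.name, (a.start - rotation) % n, (a.end - rotation) % n,
                           a.strand, a.product)
            for a in annotations
        ]

    annotations.sort(key=lambda a: a.start)
    identifier = f"synthetic_{group}_s{seed}_{strand}{'_wrap' if circular_wrap else ''}"
    record = GenomeRecord(
        identifier=identifier,
        sequence=genome_seq,
        circular=circular,
        annotations=tuple(annotations),
    )
    truth = SyntheticTruth(
        seed=seed,
        group=group,
        region_length=region_length,
        gc=gc,
        planted_m10_start=m10_start,
        planted_m35_start=m35_start,
        planted_box_starts=tuple(sorted(box_starts)),
        genome_strand_of_dnaA=strand,
        circular_wrap=circular_wrap,
    )
    return record, truth


def generate_panel(
    counts: dict[str, int],
    base_seed: int,
    region_length: int = 300,
    gc: float = 0.44,
    params: ScanParams | None = None,
) -> list[tuple[GenomeRecord, SyntheticTruth]]:
    """Deterministic panel of loci; per-locus seeds are base_seed + index.

    Groups are emitted in fixed order (I, II, III, IV) regardless of the
    mapping's insertion order; genome strand alternates and every third
    locus wraps the origin, exercising all extraction paths.
    """
    for group, n in counts.items():
        if group not in GROUP_ORDER:
            raise ValueError(f"unknown group {group!r}")
        if n < 0:
            raise ValueError(f"negative count for group {group}")
    panel: list[tuple[GenomeRecord, SyntheticTruth]] = []
    index = 0
    for group in GROUP_ORDER:
        for _ in range(counts.get(group, 0)):
            panel.append(
                generate_locus(
                    group,
                    seed=base_seed + index,
                    region_length=region_length,
                    gc=gc,
                    strand="+-"[index % 2],
                    circular_wrap=(index % 3 == 2),
                    params=params,
                )
            )
            index += 1
    return panel
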