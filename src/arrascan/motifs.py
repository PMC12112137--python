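"""Fixed-width motif matching against promoter and DnaA-box consensi.

The scanners are deliberately consensus/Hamming based: the classification
this package supports rests on exact mismatch counts against the canonical
SigA −10 (TATAAT) and −35 (TTGACA) hexamers and on a proportional
similarity to a 9-bp DnaA-box consensus, not on a trained weight matrix.
``N`` counts as a mismatch at its position, always.

All offsets index the :class:`~arrascan.genome_io.TargetRegion` string
(the strand antisense to dnaA); promoter search runs only on that strand,
DnaA-box search on both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .genome_io import TargetRegion
from .sequences import revcomp, validate_alphabet

SAME_STRAND = "+"
OPPOSITE_STRAND = "-"


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the promoter and DnaA-box scans.

    Defaults encode the canonical SigA promoter consensus, mismatch budgets
    matching the loosest accepted candidates (−10 ≤ 1 mm, −35 ≤ 2 mm), a
    15–18 bp spacer window around the canonical spacing, and the
    B. subtilis 9-mer DnaA-box consensus TTATCCACA with a ≥7/9 match
    threshold.  The box consensus is a configurable stand-in, never
    hard-coded into downstream logic.
    """

    consensus_m10: str = "TATAAT"
    consensus_m35: str = "TTGACA"
    max_mm10: int = 1
    max_mm35: int = 2
    spacer_range: tuple[int, int] = (15, 18)
    box_consensus: str = "TTATCCACA"
    box_length: int = 9
    min_box_matches: int = 7
    tss_offset: int = 7

    def __post_init__(self) -> None:
        validate_alphabet(self.consensus_m10, what="consensus_m10")
        validate_alphabet(self.consensus_m35, what="consensus_m35")
        validate_alphabet(self.box_consensus, what="box_consensus")
        if len(self.consensus_m10) != 6 or len(self.consensus_m35) != 6:
            raise ValueError("promoter consensus elements must be hexamers")
        if not 0 <= self.max_mm10 <= 6 or not 0 <= self.max_mm35 <= 6:
            raise ValueError("mismatch budgets must lie in [0, 6]")
        lo, hi = self.spacer_range
        if lo > hi or lo < 0:
            raise ValueError(f"spacer_range {self.spacer_range} is empty or negative")
        if len(self.box_consensus) != self.box_length:
            raise ValueError("box_consensus length must equal box_length")
        if not 0 <= self.min_box_matches <= self.box_length:
            raise ValueError("min_box_matches must lie in [0, box_length]")
        if self.tss_offset < 1:
            raise ValueError("tss_offset must be positive")


@dataclass(frozen=True)
class PromoterCandidate:
    """A paired −35/−10 hexamer hit on the region's own strand."""

    m10_start: int
    m10_seq: str
    mm10: int
    m35_start: int
    m35_seq: str
    mm35: int
    spacer: int
    predicted_tss: int

    def __post_init__(self) -> None:
        if self.spacer != self.m10_start - (self.m35_start + 6):
            raise ValueError("spacer inconsistent with element offsets")


@dataclass(frozen=True, order=True)
class DnaABoxHit:
    """A DnaA binding-site match; ``orientation`` is relative to the region
    strand ('+' same-strand, '-' opposite-strand)."""

    start: int
    orientation: str = "+"
    end: int = 0
    seq: str = ""
    matches: int = 0
    similarity: float = 0.0


def count_mismatches(observed: str, consensus: str) -> int:
    """Hamming distance over {A,C,G,T,N}; any N is a mismatch at its position."""
    if len(observed) != len(consensus):
        raise ContractError(
            f"length mismatch: {len(observed)} vs {len(consensus)}"
        )
    return sum(
        1 for o, c in zip(observed, consensus) if o != c or o == "N" or c == "N"
    )


def _region_seq(region: TargetRegion | str) -> str:
    return region.sequence if isinstance(region, TargetRegion) else region


def find_dnaa_boxes(region: TargetRegion | str, params: ScanParams | None = None) -> list[DnaABoxHit]:
    """All box-width windows, both orientations, with ≥ ``min_box_matches``
    agreements to the box consensus; overlapping hits are all kept.

    Sorted by start then orientation (same-strand before opposite-strand).
    A region shorter than the box width yields an empty list.
    """
    params = params or ScanParams()
    seq = _region_seq(region)
    k = params.box_length
    consensus = params.box_consensus
    rc_consensus = revcomp(consensus)
    hits: list[DnaABoxHit] = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        for orientation, cons in ((SAME_STRAND, consensus), (OPPOSITE_STRAND, rc_consensus)):
            # comparing the window to revcomp(consensus) is equivalent to
            # comparing revcomp(window) to the consensus
            matches = k - count_mismatches(window, cons)
            if matches >= params.min_box_matches:
                hits.append(
                    DnaABoxHit(
                        start=start,
                        orientation=orientation,
                        end=start + k,
                        seq=window,
                        matches=matches,
                        similarity=matches / k,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.orientation))
    return hits


def scan_promoters(region: TargetRegion | str, params: ScanParams | None = None) -> list[PromoterCandidate]:
    """Exhaustive (−35, −10) pair scan on the region's own strand.

    Every pair with mm35 ≤ max_mm35, mm10 ≤ max_mm10 and spacer inside
    ``spacer_range`` is returned, sorted by total mismatches ascending,
    then |spacer − 16| ascending, then m10_start, then m35_start.  The
    predicted transcription start is ``tss_offset`` nt beyond the 3' end of
    the −10.
    """
    params = params or ScanParams()
    seq = _region_seq(region)
    lo, hi = params.spacer_range
    out: list[PromoterCandidate] = []
    for m10_start in range(len(seq) - 5):
        hex10 = seq[m10_start : m10_start + 6]
        mm10 = count_mismatches(hex10, params.consensus_m10)
        if mm10 > params.max_mm10:
            continue
        for spacer in range(lo, hi + 1):
            m35_start = m10_start - spacer - 6
            if m35_start < 0:
                continue
            hex35 = seq[m35_start : m35_start + 6]
            mm35 = count_mismatches(hex35, params.consensus_m35)
            if mm35 > params.max_mm35:
                continue
            out.append(
                PromoterCandidate(
                    m10_start=m10_start,
                    m10_seq=hex10,
                    mm10=mm10,
                    m35_start=m35_start,
                    m35_seq=hex35,
                    mm35=mm35,
                    spacer=spacer,
                    predicted_tss=m10_start + 6 + params.tss_offset - 1,
                )
            )
    out.sort(
        key=lambda c: (c.mm10 + c.mm35, abs(c.spacer - 16), c.m10_start, c.m35_start)
    )
    return out
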