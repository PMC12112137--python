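"""Group I–IV classification of promoter/DnaA-box architectures.

A locus is classified by the exact spacing between an accepted antisense
promoter's −10 hexamer and its two flanking DnaA boxes:

=======  =========================  =======================
group    gap −10 → downstream box   gap −10 → upstream box
=======  =========================  =======================
I        16 bp                      2 bp
II       14 bp                      4 bp
III      11 bp                      7 bp
=======  =========================  =======================

"Upstream of the −10" means the −35 side in the antisense reading frame
(the box between the −10 and −35); "downstream" is the opposite side.  In
all three promoter-bearing groups the distance between the facing edges of
the two boxes is then g_up + 6 + g_down = 24 bp — a conservation law every
classified call must satisfy.  Loci with promoter candidates but no
matching gap pattern are ``unclassified``; loci with no surviving promoter
candidate are group IV.

Gap matching is exact by default: a 2-bp shift is a different group, so a
tolerance would merge groups.  ``gap_tolerance`` exists for exploratory
use and defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .motifs import DnaABoxHit, PromoterCandidate

GROUPS = ("I", "II", "III", "IV", "unclassified")

#: (g_down, g_up) per promoter-bearing group
GROUP_GAPS: dict[str, tuple[int, int]] = {
    "I": (16, 2),
    "II": (14, 4),
    "III": (11, 7),
}

#: conserved facing-edge distance between the two boxes
INTERBOX_DISTANCE = 24

# flanking-box search windows; wide enough to include every defined group
MAX_G_UP = 12
MAX_G_DOWN = 20


@dataclass(frozen=True)
class GapMeasurement:
    upstream_box: DnaABoxHit
    downstream_box: DnaABoxHit
    g_up: int
    g_down: int
    interbox_gap: int


@dataclass(frozen=True)
class ArchitectureCall:
    genome_id: str
    group: str
    promoter: Optional[PromoterCandidate] = None
    upstream_box: Optional[DnaABoxHit] = None
    downstream_box: Optional[DnaABoxHit] = None
    g_up: Optional[int] = None
    g_down: Optional[int] = None
    interbox_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _pick_flank(candidates: list[tuple[int, DnaABoxHit]]) -> Optional[tuple[int, DnaABoxHit]]:
    """Best flanking box: highest similarity, then nearest the −10, then
    leftmost (a total order, so permuting the input cannot change the pick)."""
    if not candidates:
        return None
    return min(candidates, key=lambda gb: (-gb[1].matches, gb[0], gb[1].start))


def measure_gaps(
    promoter: PromoterCandidate, boxes: Sequence[DnaABoxHit]
) -> Optional[GapMeasurement]:
    """Gaps between the −10 hexamer and its nearest qualifying flanking boxes.

    The upstream box must end 0–12 nt before the −10 start (on the −35
    side); the downstream box must start 0–20 nt after the −10 end.  Box
    orientation is ignored: the architecture conserves spacing, not
    orientation.  Returns None when either flank has no qualifying box.
    """
    m10_start = promoter.m10_start
    m10_end = m10_start + 6
    up: list[tuple[int, DnaABoxHit]] = []
    down: list[tuple[int, DnaABoxHit]] = []
    for box in boxes:
        if box.end <= m10_start:
            g = m10_start - box.end
            if g <= MAX_G_UP:
                up.append((g, box))
        elif box.start >= m10_end:
            g = box.start - m10_end
            if g <= MAX_G_DOWN:
                down.append((g, box))
    best_up = _pick_flank(up)
    best_down = _pick_flank(down)
    if best_up is None or best_down is None:
        return None
    g_up, upstream = best_up
    g_down, downstream = best_down
    return GapMeasurement(
        upstream_box=upstream,
        downstream_box=downstream,
        g_up=g_up,
        g_down=g_down,
        interbox_gap=downstream.start - upstream.end,
    )


def _matches_group(gaps: GapMeasurement, pattern: tuple[int, int], tol: int) -> bool:
    g_down, g_up = pattern
    return abs(gaps.g_down - g_down) <= tol and abs(gaps.g_up - g_up) <= tol


def classify_locus(
    promoters: Sequence[PromoterCandidate],
    boxes: Sequence[DnaABoxHit],
    genome_id: str = "",
    gap_tolerance: int = 0,
) -> ArchitectureCall:
    """Classify one locus from its promoter candidates and box hits.

    Promoters are taken in their scan order (best-ranked first); the first
    candidate with a 16-bp spacer whose measured gaps match a group pattern
    fixes the call.  Candidates present but none matching → unclassified
    (the top candidate and its best-effort gaps are recorded).  No
    candidates at all → group IV.
    """
    if not promoters:
        return ArchitectureCall(genome_id=genome_id, group="IV")

    for promoter in promoters:
        if promoter.spacer != 16:
            continue
        gaps = measure_gaps(promoter, boxes)
        if gaps is None:
            continue
        for group, pattern in GROUP_GAPS.items():
            if _matches_group(gaps, pattern, gap_tolerance):
                return ArchitectureCall(
                    genome_id=genome_id,
                    group=group,
                    promoter=promoter,
                    upstream_box=gaps.upstream_box,
                    downstream_box=gaps.downstream_box,
                    g_up=gaps.g_up,
                    g_down=gaps.g_down,
                    interbox_gap=gaps.interbox_gap,
                )

    top = promoters[0]
    gaps = measure_gaps(top, boxes)
    return ArchitectureCall(
        genome_id=genome_id,
        group="unclassified",
        promoter=top,
        upstream_box=gaps.upstream_box if gaps else None,
        downstream_box=gaps.downstream_box if gaps else None,
        g_up=gaps.g_up if gaps else None,
        g_down=gaps.g_down if gaps else None,
        interbox_gap=gaps.interbox_gap if gaps else None,
    )
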