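"""Transcript-length arithmetic for run-off and terminator-bounded templates.

Lengths are inclusive counts of transcribed template positions: a run-off
product spans the start site through the template edge; a terminated
product spans the start site through the terminator's recorded last
transcribed base.  A readthrough-permissive terminator lets polymerase
continue to later terminators (or to the template end); the first
non-permissive terminator ends the enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ContractError


@dataclass(frozen=True)
class Terminator:
    """``position`` is the last transcribed base; readthrough marks leaky
    termination (a fraction of polymerases continue past it)."""

    position: int
    readthrough: bool = False


@dataclass(frozen=True)
class TranscriptionLayout:
    template_interval: tuple[int, int]  # 0-based half-open
    tss: int
    direction: str  # "+" or "-"
    terminators: tuple[Terminator, ...] = ()

    def __post_init__(self) -> None:
        start, end = self.template_interval
        if start >= end:
            raise ContractError(f"empty template interval ({start}, {end})")
        if self.direction not in "+-":
            raise ContractError(f"direction must be '+' or '-', got {self.direction!r}")
        if not start <= self.tss < end:
            raise ContractError(
                f"tss {self.tss} outside template [{start}, {end})"
            )
        for t in self.terminators:
            if not start <= t.position < end:
                raise ContractError(f"terminator at {t.position} outside template")
            if self._distance(t.position) < 1:
                raise ContractError(
                    f"terminator at {t.position} not downstream of tss {self.tss}"
                )

    def _distance(self, position: int) -> int:
        """Inclusive transcribed length from the tss through ``position``."""
        if self.direction == "+":
            return position - self.tss + 1
        return self.tss - position + 1


@dataclass(frozen=True)
class TranscriptIsoform:
    length: int
    end_kind: str  # "runoff" or "terminated"
    terminator_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("transcript length must be positive")


def runoff_length(layout: TranscriptionLayout) -> TranscriptIsoform:
    """Run-off product length on a terminator-free template.

    Counts template positions from the tss to the template edge in the
    transcription direction, inclusive of both.
    """
    if layout.terminators:
        raise ContractError("runoff_length requires a terminator-free layout")
    start, end = layout.template_interval
    if layout.direction == "+":
        length = end - layout.tss
    else:
        length = layout.tss - start + 1
    return TranscriptIsoform(length=length, end_kind="runoff")


def isoform_lengths(layout: TranscriptionLayout) -> list[TranscriptIsoform]:
    """Enumerate transcript isoforms over the layout's terminators.

    Terminators must be given in increasing distance from the tss.  One
    terminated isoform is produced per terminator reached; enumeration stops
    at the first non-readthrough terminator.  A run-off isoform is appended
    only when every terminator permits readthrough (or there are none).
    """
    distances = [layout._distance(t.position) for t in layout.terminators]
    if any(b <= a for a, b in zip(distances, distances[1:])):
        raise ContractError("terminators must be sorted by distance from the tss")

    out: list[TranscriptIsoform] = []
    for index, (term, dist) in enumerate(zip(layout.terminators, distances)):
        out.append(TranscriptIsoform(length=dist, end_kind="terminated",
                                     terminator_index=index))
        if not term.readthrough:
            return out
    # every terminator (if any) was leaky: polymerase reaches the template end
    start, end = layout.template_interval
    runoff = end - layout.tss if layout.direction == "+" else layout.tss - start + 1
    out.append(TranscriptIsoform(length=runoff, end_kind="runoff"))
    return out
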