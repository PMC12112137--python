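"""Shared fixtures and independent brute-force oracles.

The oracles re-derive scanner outputs by naive enumeration and stay
independent of the package's scan implementations: they are the reference
the scanners are checked against.
"""

from __future__ import annotations

import pytest

from arrascan.genome_io import GeneAnnotation, GenomeRecord

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    """Independent mismatch count (N never matches anything)."""
    assert len(a) == len(b)
    return sum(x != y or "N" in (x, y) for x, y in zip(a, b))


def oracle_boxes(seq: str, consensus: str, min_matches: int):
    """Every window, both orientations, with enough consensus agreements.

    Returns (start, orientation, matches) triples sorted by (start,
    orientation).  Opposite-strand matching reads the reverse complement of
    the window against the consensus.
    """
    k = len(consensus)
    out = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        same = k - hamming(window, consensus)
        if same >= min_matches:
            out.append((start, "+", same))
        opp = k - hamming(naive_revcomp(window), consensus)
        if opp >= min_matches:
            out.append((start, "-", opp))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def oracle_promoters(seq: str, m10: str, m35: str, max_mm10: int, max_mm35: int,
                     spacer_lo: int, spacer_hi: int):
    """Every qualifying (−35, −10) pair as (m35_start, m10_start, mm35,
    mm10, spacer), unsorted set semantics."""
    out = set()
    for m35_start in range(len(seq) - 5):
        h35 = seq[m35_start : m35_start + 6]
        mm35 = hamming(h35, m35)
        if mm35 > max_mm35:
            continue
        for spacer in range(spacer_lo, spacer_hi + 1):
            m10_start = m35_start + 6 + spacer
            if m10_start + 6 > len(seq):
                continue
            h10 = seq[m10_start : m10_start + 6]
            mm10 = hamming(h10, m10)
            if mm10 <= max_mm10:
                out.add((m35_start, m10_start, mm35, mm10, spacer))
    return out


MINI_GENBANK = """\
LOCUS       minilocus                 30 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  minimal synthetic test locus.
ACCESSION   minilocus
VERSION     minilocus
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     CDS             1..9
                     /gene="rpmH"
     CDS             20..28
                     /gene="dnaA"
ORIGIN
        1 aaaaaaaaaa cgtacgtacc cccccccctt
//
"""

SINGLE_CDS_GENBANK = """\
LOCUS       solo                      24 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  single-gene synthetic test locus.
ACCESSION   solo
VERSION     solo
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     CDS             4..15
                     /gene="dnaA"
ORIGIN
        1 acgtacgtac gtacgtacgt acgt
//
"""


@pytest.fixture
def mini_genbank_path(tmp_path):
    path = tmp_path / "mini.gbk"
    path.write_text(MINI_GENBANK)
    return path


@pytest.fixture
def single_cds_genbank_path(tmp_path):
    path = tmp_path / "solo.gbk"
    path.write_text(SINGLE_CDS_GENBANK)
    return path


@pytest.fixture
def mini_genome() -> GenomeRecord:
    """The 30-nt worked example: rpmH [0,9)+, dnaA [19,28)+, intergenic
    bases 9..19 = ACGTACGTAC."""
    return GenomeRecord(
        "minilocus",
        "AAAAAAAAA" + "ACGTACGTAC" + "CCCCCCCCC" + "TT",
        False,
        (
            GeneAnnotation("rpmH", 0, 9, "+"),
            GeneAnnotation("dnaA", 19, 28, "+"),
        ),
    )


def flip_genome(genome: GenomeRecord) -> GenomeRecord:
    """Reverse-complement a genome and mirror all annotations."""
    n = len(genome.sequence)
    return GenomeRecord(
        genome.identifier,
        naive_revcomp(genome.sequence),
        genome.circular,
        tuple(
            GeneAnnotation(a.name, n - a.end, n - a.start,
                           "-" if a.strand == "+" else "+", a.product)
            for a in genome.annotations
        ),
    )
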