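#!/usr/bin/env python
"""Transcript-length arithmetic for the three template layouts.

Predicts product sizes for (1) a run-off template carrying the dnaA
promoter, (2) an engineered dual-terminator template carrying both the
dnaA and the antisense promoter, and (3) the in vivo antisense locus with
a leaky terminator in the intergenic region and a hard terminator beyond
rpmH.  Coordinates are synthetic, constructed to the template sizes the
products were measured on; the module computes lengths, it does not infer
genomic start sites.  Writes results/transcripts.tsv.
"""

from pathlib import Path

import pandas as pd

from arrascan import Terminator, TranscriptionLayout, isoform_lengths, runoff_length


def main() -> None:
    rows = []

    runoff = runoff_length(TranscriptionLayout((0, 262), tss=10, direction="+"))
    rows.append(("runoff_template", "PdnaA", runoff.length, runoff.end_kind))

    sense = isoform_lengths(TranscriptionLayout(
        (0, 948), tss=100, direction="+",
        terminators=(Terminator(399, readthrough=False),)))
    antisense = isoform_lengths(TranscriptionLayout(
        (0, 948), tss=847, direction="-",
        terminators=(Terminator(348, readthrough=False),)))
    rows.append(("dual_terminator_template", "PdnaA", sense[0].length,
                 sense[0].end_kind))
    rows.append(("dual_terminator_template", "ParrA", antisense[0].length,
                 antisense[0].end_kind))

    in_vivo = isoform_lengths(TranscriptionLayout(
        (0, 800), tss=0, direction="+",
        terminators=(Terminator(269, readthrough=True),
                     Terminator(666, readthrough=False)),
    ))
    for iso in in_vivo:
        rows.append(("in_vivo_antisense_locus", "ParrA", iso.length, iso.end_kind))

    table = pd.DataFrame(rows, columns=["template", "promoter", "length_nt",
                                        "end_kind"])
    out = Path(__file__).resolve().parents[1] / "results"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "transcripts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
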