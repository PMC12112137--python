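"""Exception hierarchy for arrascan.

All package errors derive from :class:`ArrascanError` so callers can catch
one base class; the pipeline additionally distinguishes per-locus anchor
problems (recorded as skipped rows) from fatal input problems.
"""


class ArrascanError(Exception):
    """Base class for all arrascan errors."""


class InputError(ArrascanError):
    """A file is missing or unreadable."""


class FormatError(ArrascanError):
    """A file parses under no supported standard or carries no sequence."""


class AnchorGeneError(ArrascanError):
    """A required anchor gene (dnaA or rpmH) is absent from a record."""


class AmbiguousAnchorError(ArrascanError):
    """More than one annotation matches an anchor gene symbol."""


class GeometryError(ArrascanError):
    """Gene geometry makes the intergenic region undefined (overlap, or a
    wrapping interval on a linear record)."""


class ContractError(ArrascanError):
    """A caller violated an operation's precondition."""


class GenerationError(ArrascanError):
    """The synthetic-locus generator exhausted its redraw budget."""
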