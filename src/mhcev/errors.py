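"""Exception hierarchy shared across the package."""


class MhcevError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MhcevError):
    """Malformed input file (ragged alignment, bad FASTA, bad TSV)."""


class MetadataError(MhcevError):
    """Sequence id missing from, or duplicated in, the metadata table."""


class FrameError(MhcevError):
    """Alignment length is not a multiple of three."""


class AlphabetError(MhcevError):
    """Sequence contains a character outside {A,C,G,T,N,-}."""


class SiteError(MhcevError):
    """Codon unsuitable for site counting (stop or ambiguous)."""


class SaturationError(MhcevError):
    """Distance correction undefined (proportion of differences too high)."""


class SizeError(MhcevError):
    """Too few sequences/taxa for the requested operation."""


class CladeError(MhcevError):
    """Tip set is not monophyletic, or clade has no stem branch."""


class ShapeError(MhcevError):
    """Tree violates a shape requirement (e.g. not ultrametric)."""


class LabelingError(MhcevError):
    """A tip lacks a required state or trait value."""


class TestError(MhcevError):
    """A statistical test is undefined for the given data."""


class FitError(MhcevError):
    """Numerical model fitting failed to converge."""
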