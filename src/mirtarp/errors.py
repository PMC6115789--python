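"""Exception hierarchy shared across the package."""


class MirtarpError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(MirtarpError, ValueError):
    """Raised when a FASTA file yields no parseable record."""


class ParameterError(MirtarpError, ValueError):
    """Raised when a user-supplied parameter is outside its valid range."""


class InvalidStructureError(MirtarpError, ValueError):
    """Raised when a pair list violates the geometric rules of a structure."""
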