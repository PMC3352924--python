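"""Exception hierarchy shared by all nbsarch modules."""


class NbsArchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NbsArchError, ValueError):
    """A file does not conform to its declared format (FASTA/GFF3/TSV)."""


class ValidationError(NbsArchError, ValueError):
    """Structurally valid input that violates a semantic contract."""


class CoordinateError(NbsArchError, ValueError):
    """A coordinate falls outside the sequence it refers to."""


class InputError(NbsArchError, ValueError):
    """An argument value outside an operation's documented domain."""
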