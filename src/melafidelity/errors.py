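"""Exception hierarchy shared across the package."""


class MelafidelityError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MelafidelityError):
    """A file does not conform to the expected dialect (empty, missing columns...)."""


class ParseError(MelafidelityError):
    """A single cell or field could not be parsed; the message names the location."""


class ConsistencyError(MelafidelityError):
    """Fields of a record contradict each other (e.g. 3-mer context vs reference base)."""


class DegenerateSampleError(MelafidelityError):
    """A sample is unusable for the requested computation (e.g. all-zero column)."""


class UndefinedCorrelationError(MelafidelityError):
    """A Pearson correlation is requested on a zero-variance vector."""
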