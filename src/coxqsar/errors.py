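"""Exception hierarchy shared across the package.

The pipeline maps these onto process exit codes: configuration problems
exit 2, data problems exit 3, stage-ordering problems exit 4.
"""


class CoxQsarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoxQsarError):
    """Invalid option, parameter out of range, or malformed generator spec."""


class DataError(CoxQsarError):
    """Problems with input data content or shape."""


class FormatError(DataError):
    """Structural problem in an input file (missing column, bad header)."""


class ParseError(FormatError):
    """Unparseable cell; message carries row and column."""


class DomainError(DataError, ValueError):
    """Numeric argument outside the mathematical domain of an operation."""


class DegenerateInputError(DataError):
    """Zero-variance vector where a correlation is requested."""


class CollinearityError(DataError):
    """Rank-deficient regression design matrix."""


class EmptySelectionError(DataError):
    """Descriptor selection retained nothing; modelling cannot proceed."""


class DimensionError(DataError):
    """Mismatched lengths between paired inputs (fingerprints, coordinates)."""


class MissingDescriptorError(DataError, KeyError):
    """A model requires a descriptor the compound does not carry."""


class OrderingError(CoxQsarError):
    """A pipeline stage was invoked before its prerequisite stage."""
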