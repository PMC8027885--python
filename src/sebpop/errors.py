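"""Exception types shared across the package."""


class SebpopError(Exception):
    """Base class for all package errors."""


class ParameterError(SebpopError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(SebpopError, ValueError):
    """A configuration block is inconsistent or infeasible."""


class DataError(SebpopError, ValueError):
    """Input data violate a precondition (shapes, labels, coverage)."""


class RangeError(SebpopError, ValueError):
    """A genomic coordinate falls outside the variant map."""


class MetadataError(SebpopError, ValueError):
    """Sample metadata are missing or malformed."""


class ModelViolationError(SebpopError, ValueError):
    """Observed quantities are incompatible with the assumed model."""
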