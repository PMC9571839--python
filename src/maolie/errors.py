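"""Exception hierarchy shared across the package."""


class MaolieError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MaolieError, ValueError):
    """An operation received arguments that violate its preconditions."""


class FormatError(MaolieError, ValueError):
    """A file does not conform to the documented dialect."""


class DegenerateFitError(MaolieError, ValueError):
    """The calibration design matrix is rank-deficient."""


class ConfigurationError(MaolieError, ValueError):
    """An annotation or configuration entry cannot be resolved."""


class GenerationError(MaolieError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
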