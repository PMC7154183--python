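"""Exception hierarchy shared across the package."""


class QuailFCMError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(QuailFCMError, ValueError):
    """A generator or run configuration violates its invariants."""


class SchemaError(QuailFCMError, ValueError):
    """A table is missing required columns or has malformed values."""


class InvalidPlateError(QuailFCMError, ValueError):
    """An assay plate cannot be resolved into B0/NSB/standards."""


class InsufficientDataError(QuailFCMError, ValueError):
    """Too few points, standards, plates or birds for the requested statistic."""
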