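"""Exception hierarchy shared by all plankform modules.

The CLI maps these onto exit codes: ValidationError -> 2, DataError -> 3,
FitError -> 4.  Library users catch the specific subclasses.
"""


class PlankformError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PlankformError, ValueError):
    """A configuration or argument violates a documented invariant."""


class DataError(PlankformError, ValueError):
    """Input data are malformed or inconsistent."""


class UnknownTechniqueError(DataError):
    """A technique code outside the seven recognised labels."""


class MalformedInputError(DataError):
    """Structurally broken input (missing channels, timestamp gaps, duplicates)."""


class FitError(PlankformError, RuntimeError):
    """Model fitting failed."""


class SeparabilityError(FitError):
    """Threshold-node fit requested on classes that overlap on the chosen variable."""


class ModelVersionError(PlankformError, RuntimeError):
    """A persisted model file is truncated, foreign, or from an incompatible version."""
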