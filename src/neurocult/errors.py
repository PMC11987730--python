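"""Exception hierarchy.

Three broad classes map onto CLI exit codes: configuration/validation
problems (exit 2), data problems discovered while processing (exit 3),
and anything else (exit 1).
"""


class NeurocultError(Exception):
    """Base class for all package errors."""


class ValidationError(NeurocultError, ValueError):
    """A parameter or configuration value violates its invariant."""


class ConfigurationError(ValidationError):
    """An unknown method name or inconsistent configuration."""


class MissingMetadataError(ValidationError):
    """Required metadata (e.g. the physical pixel size) was not supplied."""


class DataError(NeurocultError):
    """The supplied data cannot be processed."""


class PlacementError(DataError):
    """Soma placement failed; carries the count that was achieved."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} requested somata "
            f"without overlap; reduce n_cells or soma radii"
        )


class DegenerateThresholdError(DataError):
    """Automatic thresholding is undefined (e.g. a constant image)."""


class DegenerateDataError(DataError):
    """A statistic is undefined for the data (e.g. zero variance)."""


class InsufficientSampleError(DataError):
    """A group has too few observations for the requested test."""


class ReferentialIntegrityError(DataError):
    """An object references an id that does not exist."""


class FormatError(DataError):
    """A file does not conform to the expected tabular format."""


class DomainError(DataError):
    """A value lies outside the mathematical domain of an operation."""
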