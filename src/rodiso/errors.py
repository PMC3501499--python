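"""Exception hierarchy shared across the package."""


class RodisoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RodisoError, ValueError):
    """An argument violates a precondition (e.g. non-positive isotope ratio)."""


class MissingDataError(RodisoError, ValueError):
    """A required isotope value is absent on a record."""


class EmptySelectionError(RodisoError, ValueError):
    """A filter or grouping produced no eligible records."""


class DegenerateVarianceError(RodisoError, ValueError):
    """A statistical test cannot be computed (zero variance / all ties)."""


class InsufficientDataError(RodisoError, ValueError):
    """Too few observations for the requested procedure."""


class RegistryConflictError(RodisoError, KeyError):
    """Attempt to register a calibration under an existing name."""


class NotFoundError(RodisoError, KeyError):
    """Lookup of an unknown name in a registry."""


class FormatError(RodisoError, ValueError):
    """A dataset file violates the canonical CSV schema."""


class ConfigError(RodisoError, ValueError):
    """A simulation or pipeline configuration is invalid."""
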