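"""Exception hierarchy.

All package errors derive from :class:`MilletSWBError` so callers can catch
one base class; the CLI maps subclasses onto distinct exit codes.
"""


class MilletSWBError(Exception):
    """Base class for all milletswb errors."""


class InvalidInputError(MilletSWBError, ValueError):
    """A runtime input (weather record, flux, measurement) violates its contract."""


class InvalidConfigError(MilletSWBError, ValueError):
    """A configuration value (crop parameter, soil layer, spec) is inconsistent."""


class MeasurementError(InvalidInputError):
    """A field measurement is physically impossible (e.g. PAR below > above)."""


class DegenerateFitError(MilletSWBError, ValueError):
    """A regression has no information content (all-zero regressor, no usable points)."""


class UndefinedStatisticError(MilletSWBError, ValueError):
    """A goodness-of-fit statistic is undefined for the given series."""


class SimulationError(MilletSWBError, RuntimeError):
    """A season simulation could not be completed."""
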