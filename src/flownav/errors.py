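"""Exception types shared across the package."""


class FlownavError(Exception):
    """Base class for all flownav errors."""


class CompensationInfeasibleError(FlownavError):
    """Lateral flow exceeds the self-speed; no heading can cancel drift."""


class NoFeasibleHeadingError(FlownavError):
    """No initial heading brings the traveller within the arrival tolerance."""


class OutOfRangeError(FlownavError):
    """A closed-form expression was requested outside its domain of validity."""


class OutOfDomainError(FlownavError):
    """A wind-field query fell outside the gridded space-time domain."""


class MissingVariableError(FlownavError):
    """A wind file lacks a recognisable eastward/northward wind variable."""


class LevelNotFoundError(FlownavError):
    """The requested pressure level is not present in the wind file."""


class DomainNotCoveredError(FlownavError):
    """The wind file does not cover the requested bounding box or time span."""


class PoleCrossingError(FlownavError):
    """A spherical integration step would reach or cross a geographic pole."""


class NoDuskError(FlownavError):
    """Civil dusk does not occur (polar day or polar night)."""
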