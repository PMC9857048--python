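"""Exception hierarchy for the psmalesion pipeline."""


class PsmaLesionError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PsmaLesionError, ValueError):
    """An invalid configuration field; the message names the field."""


class GeometryError(PsmaLesionError, ValueError):
    """A region of interest does not fit inside the voxel grid."""


class DegenerateSignalError(PsmaLesionError, ValueError):
    """The image region carries no usable signal (e.g. all zeros)."""


class ReferenceUptakeError(PsmaLesionError, ValueError):
    """Organ reference uptakes violate their ordering/positivity invariants."""


class UndefinedStatisticError(PsmaLesionError, ValueError):
    """A statistic is undefined for the given input (zero variance, single class...)."""


class SchemaError(PsmaLesionError, ValueError):
    """A tabular input does not conform to the expected column schema."""
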