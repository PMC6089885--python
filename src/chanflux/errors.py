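"""Exception hierarchy shared by all analysis stages."""


class ChanfluxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChanfluxError):
    """A structure/trajectory file could not be read in the expected format."""


class SelectionError(ChanfluxError):
    """An atom selection expression resolved to nothing or is malformed."""


class ConsistencyError(ChanfluxError):
    """Inputs disagree with each other (atom counts, timestamps, bin edges)."""


class ParameterError(ChanfluxError):
    """A numeric parameter is outside its valid domain."""


class GeometryError(ChanfluxError):
    """A geometric construction is degenerate (collinear anchors etc.)."""


class InsufficientDataError(ChanfluxError):
    """Not enough frames/samples to run the requested estimator."""


class DegenerateInputError(ChanfluxError):
    """Input is structurally valid but carries no usable signal."""


class EmptySliceError(ChanfluxError):
    """No wall atoms near the requested pore slice."""


class MappingError(ChanfluxError):
    """Residue labels could not be mapped between coordinate systems."""


class InputError(ChanfluxError):
    """Generic invalid user input (empty sample, overlapping sets, ...)."""
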