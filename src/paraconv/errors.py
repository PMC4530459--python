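"""Exception hierarchy shared across the package."""


class ParaconvError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(ParaconvError):
    """Rows of an alignment do not all have the same length."""


class IdentifierError(ParaconvError):
    """Duplicate, missing, or mismatched sequence identifiers."""


class CoordinateError(ParaconvError):
    """Column coordinates outside the alignment (coordinates are 1-based inclusive)."""


class AlphabetError(ParaconvError):
    """Operation applied to an alignment with an incompatible alphabet."""


class DegenerateSequenceError(ParaconvError):
    """A sequence has no usable characters for the requested statistic."""


class ModelError(ParaconvError):
    """Unknown substitution model or invalid model parameters."""


class TreeError(ParaconvError):
    """Malformed tree, label mismatch, or unsatisfiable constraint."""


class NumericError(ParaconvError):
    """Non-finite likelihood or failed numerical optimization."""


class ConfigurationError(ParaconvError):
    """Inconsistent combination of analysis settings."""
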