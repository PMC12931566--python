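"""Exception hierarchy for the polychromia package."""


class PolychromiaError(Exception):
    """Base class for all package errors."""


class FormatError(PolychromiaError):
    """Input file could not be decoded as an image of the expected layout."""


class UnsupportedDepthError(PolychromiaError):
    """Image bit depth is not 8 bits per channel."""


class EmptyROIError(PolychromiaError):
    """A region of interest selects no pixels."""


class ShapeMismatchError(PolychromiaError):
    """Planes or masks that must share dimensions do not."""


class InconsistencyError(PolychromiaError):
    """Inputs that must agree (e.g. equal pixel counts) do not."""


class ConfigError(PolychromiaError):
    """Invalid analysis or scene configuration."""
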