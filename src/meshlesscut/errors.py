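"""Exception hierarchy shared across the package."""


class MeshlessCutError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MeshlessCutError, ValueError):
    """A numeric argument violates its precondition (sign, range, shape)."""


class FormatError(MeshlessCutError, ValueError):
    """A file could not be parsed; the message names the offending part."""


class InvalidChordError(MeshlessCutError, ValueError):
    """Chord endpoints coincide; no side classification is possible."""


class NoCutError(MeshlessCutError, ValueError):
    """The cutting path has fewer than two vertices."""


class UnsupportedPathError(MeshlessCutError, ValueError):
    """The cutting path is self-intersecting or not edge-connected."""


class InvalidScalpelError(MeshlessCutError, ValueError):
    """Scalpel tip/handle/vertical configuration is degenerate."""


class SingularMomentError(MeshlessCutError, ValueError):
    """An unregularized MLS moment matrix is singular."""


class NumericalBlowupError(MeshlessCutError, ArithmeticError):
    """Non-finite force or displacement encountered during integration."""


class InvalidInputError(MeshlessCutError, ValueError):
    """Generic invalid input (empty sample sets, mismatched series)."""


class ConfigError(MeshlessCutError, ValueError):
    """Simulation configuration failed validation; message lists fields."""
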