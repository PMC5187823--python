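"""Exception hierarchy."""


class SilkspacerError(Exception):
    """Base class for all package errors."""


class InputError(SilkspacerError):
    """Invalid user-supplied values (sequences, angles, occupancies...)."""


class GeometryError(SilkspacerError):
    """Degenerate or insufficient geometry (collinear atoms, < 3 points...)."""


class ConstructionError(SilkspacerError):
    """A structure could not be built (e.g. steric clash in a fibril)."""


class ConfigError(SilkspacerError):
    """Malformed run or ladder configuration."""


class FormatError(SilkspacerError):
    """Malformed structure file (inconsistent models, bad records)."""


class ClassificationError(SilkspacerError):
    """A classifier received insufficient reference data or angles."""


class NumericalError(SilkspacerError):
    """An iterative procedure failed to converge."""
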