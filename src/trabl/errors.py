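"""Exception hierarchy for the trabl package."""


class TrablError(Exception):
    """Base class for all trabl-specific errors."""


class MeshFormatError(TrablError):
    """A mesh file could not be read or parsed in the declared format."""


class DegenerateInputError(TrablError):
    """An input collapsed below the minimum required by the operation."""


class ConfigError(TrablError):
    """A case-configuration file is missing fields or violates its schema."""


class DegenerateGeometryError(TrablError):
    """Points are coplanar/collinear where a 3D fit is required."""


class FrameError(TrablError):
    """The anatomical coordinate frame could not be constructed."""


class UndefinedRatioError(TrablError):
    """A bone-loss ratio is undefined because the reference area is zero."""


class PhantomError(TrablError):
    """A phantom specification would produce degenerate geometry."""
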