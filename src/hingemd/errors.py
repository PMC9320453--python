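"""Exception hierarchy shared across the package."""


class HingemdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HingemdError, ValueError):
    """A structure/trajectory file violates its format contract."""


class EmptyInputError(HingemdError, ValueError):
    """An input that must be non-empty (models, frames, series) is empty."""


class ConfigError(HingemdError, ValueError):
    """Invalid configuration: unknown domain, bad parameter, overlapping ranges."""


class EmptySelectionError(HingemdError, ValueError):
    """An atom selection resolved to zero atoms."""


class ShapeError(HingemdError, ValueError):
    """Coordinate arrays with incompatible shapes or atom counts."""


class DegenerateGeometryError(HingemdError, ValueError):
    """Geometry too degenerate for the requested operation.

    Raised for superposition with fewer than three or collinear fit points,
    and for angles whose defining vectors have zero length.
    """
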