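"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`SwitchscapeError`
so callers (and the CLI) can distinguish input problems from genuine bugs.
"""


class SwitchscapeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SwitchscapeError):
    """A structure or table file could not be parsed; names the offending line."""


class ConsistencyError(SwitchscapeError):
    """Frames/models or sidecar data disagree with the topology."""


class SelectionError(SwitchscapeError):
    """Bad selection expression or invalid atom-group combination."""


class GeometryError(SwitchscapeError):
    """Degenerate geometry (e.g. collinear points defining a dihedral)."""


class SizeError(SwitchscapeError):
    """An input is too small for the requested operation."""


class DihedralError(SwitchscapeError):
    """A requested dihedral angle cannot be built from the available atoms."""


class AlignmentError(SwitchscapeError):
    """Label mismatch between two dihedral series or feature sets."""


class ParameterError(SwitchscapeError):
    """Missing charge / Lennard-Jones parameters for an energetics call."""


class BlockSizeError(SwitchscapeError):
    """Too few frames for the requested block-averaging length."""


class SpecError(SwitchscapeError):
    """Invalid synthetic-data or potential specification."""


class BiasError(SwitchscapeError):
    """Empty or inconsistent metadynamics bias."""


class SurfaceError(SwitchscapeError):
    """Degenerate free-energy surface (fully masked / no basin)."""


class DivergenceError(SwitchscapeError):
    """Non-finite state or gradient during sampling; carries the step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ConfigError(SwitchscapeError):
    """Invalid run configuration (unknown key, missing file, bad value)."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key
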