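"""Exception hierarchy shared across the package."""


class ElbowExtError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ElbowExtError, ValueError):
    """Invalid user input: malformed config, bad table schema, out-of-range value."""


class GeometryError(ElbowExtError):
    """Degenerate or impossible muscle-path geometry (e.g. endpoint inside a wrap object)."""


class ParameterError(ElbowExtError):
    """Inconsistent musculotendon architecture parameters (e.g. non-positive tendon slack length)."""


class EquilibriumError(ElbowExtError):
    """The isometric muscle-tendon force balance has no root in the admissible fiber-length bracket."""
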