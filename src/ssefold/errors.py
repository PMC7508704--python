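"""Exception hierarchy for ssefold.

Every stage raises a subclass of :class:`SsefoldError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class SsefoldError(Exception):
    """Base class for all ssefold errors."""


class DotBracketError(SsefoldError):
    """Malformed dot-bracket text (unbalanced brackets, bad characters)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class InputError(SsefoldError):
    """Inconsistent user input (e.g. sequence/structure length mismatch)."""


class FormatError(SsefoldError):
    """Unreadable or truncated structure file."""


class AnnotationError(SsefoldError):
    """Base-pair annotation failed (e.g. missing ring atoms)."""


class DecompositionError(SsefoldError):
    """Secondary structure cannot be decomposed into SSEs (no pairs)."""


class LibraryError(SsefoldError):
    """Template-library construction, persistence or update failure."""


class AssemblyError(SsefoldError):
    """No template for an SSE, or the fragment join is ill-posed."""


class GeometryError(SsefoldError):
    """Degenerate geometry (too few / collinear superposition anchors)."""


class FixtureError(SsefoldError):
    """Invalid synthetic-fixture request."""


class MinimizationError(SsefoldError):
    """Non-finite energy during gradient descent."""


class ComparisonError(SsefoldError):
    """Reference and model cannot be compared (residue/atom mismatch)."""
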