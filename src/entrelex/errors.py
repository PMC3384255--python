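"""Exception hierarchy for the toolkit.

Every error raised by entrelex derives from :class:`EntrelexError` so callers
can catch toolkit failures without masking programming errors.
"""


class EntrelexError(Exception):
    """Base class for all toolkit errors."""


class MalformedAnnotationError(EntrelexError):
    """A standoff line is syntactically invalid or contradicts the text."""


class UnresolvedReferenceError(EntrelexError):
    """A relation argument points at an annotation id that does not exist."""


class AlignmentError(EntrelexError):
    """A mention cannot be aligned to the token layer of its sentence."""


class EmptyMatrixError(EntrelexError):
    """A term-context matrix would contain no rows."""


class ParameterError(EntrelexError):
    """A numeric parameter is outside its valid range."""


class DimensionError(EntrelexError):
    """Vector operands have incompatible shapes."""


class DegenerateModelError(EntrelexError):
    """Training data does not support fitting a model (e.g. one class only)."""


class InstanceError(EntrelexError):
    """A classification instance is missing a required context element."""


class CompatibilityError(EntrelexError):
    """Model and input were built with incompatible feature configurations."""


class ConfigError(EntrelexError):
    """A generator or pipeline configuration is invalid."""


class SplitError(EntrelexError):
    """A train/test split would leave one side empty."""


class WriteError(EntrelexError):
    """Standoff output would be invalid (e.g. duplicate identifiers)."""


class ReportError(EntrelexError):
    """Two evaluation reports cannot be compared."""
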