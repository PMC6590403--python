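"""Exception and warning classes shared across the package."""


class VfaregError(Exception):
    """Base class for all package-specific errors."""


class MissingClassError(VfaregError):
    """A feature class present in the moving cloud has no counterpart in the fixed cloud."""


class EmptyFeatureError(VfaregError):
    """The moving cloud carries no nonzero form attributes and cannot drive registration."""


class DegenerateNeighborhoodError(VfaregError):
    """Neighbor positions are rank-deficient; the local affine field fit is underdetermined."""


class NonFiniteObjectiveError(VfaregError):
    """The objective returned NaN or Inf during optimization."""


class ParseError(VfaregError):
    """A point-cloud file could not be parsed; the message carries line/element context."""


class MissingAttributeWarning(UserWarning):
    """A PLY file had no integer 'attribute' property; attributes default to zero."""
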