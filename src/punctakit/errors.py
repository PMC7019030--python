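"""Exception hierarchy shared across the pipeline.

All punctakit errors derive from :class:`PunctakitError` so callers can catch
pipeline failures with a single except clause; each subclass also derives from
``ValueError`` so they behave sensibly in generic code.
"""


class PunctakitError(Exception):
    """Base class for all punctakit errors."""


class ParameterError(PunctakitError, ValueError):
    """A parameter violates a documented invariant; the message names it."""


class GeometryError(PunctakitError, ValueError):
    """A path or sample falls outside the image bounds."""


class FormatError(PunctakitError, ValueError):
    """Unsupported or malformed input file (e.g. RGB TIFF, zero pages)."""


class DegenerateInputError(PunctakitError, ValueError):
    """Input is numerically degenerate (nonpositive totals, zero averages)."""


class DesignError(PunctakitError, ValueError):
    """Statistical design is invalid (unbalanced, too few groups/subjects)."""


class NormalizationError(PunctakitError, ValueError):
    """A dendrite cannot be normalized (no puncta at the initial frame)."""


class AlignmentError(PunctakitError, ValueError):
    """Series to be pooled do not share a common time grid."""
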