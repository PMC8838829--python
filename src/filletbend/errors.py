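"""Exception types shared across the pipeline."""


class FilletBendError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FilletBendError):
    """An input file or table does not match the expected layout."""


class NoObjectError(FilletBendError):
    """No fillet object was found where one was required (empty mask,
    no arrival trigger, empty tracking window)."""


class DegenerateShapeError(FilletBendError):
    """A mask is too small or too thin for shape analysis (e.g. fewer
    than three skeleton points for the quadratic fit)."""


class DegenerateFitError(FilletBendError):
    """A classifier cannot be fitted (e.g. single-class training split)."""


class IncompleteGridError(FilletBendError):
    """A marginal mean was requested over a score grid with missing cells."""
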