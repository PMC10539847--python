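"""Exception hierarchy shared across the package.

Every error raised deliberately by slowex derives from :class:`SlowexError`,
so callers (and the CLI) can distinguish analysis failures (exit code 1)
from usage errors (exit code 2).
"""


class SlowexError(Exception):
    """Base class for all errors raised by slowex."""


class DomainError(SlowexError, ValueError):
    """An input violates a physical or mathematical precondition."""


class ConvergenceError(SlowexError, RuntimeError):
    """A root search or optimizer failed to converge."""


class PeakListError(SlowexError, ValueError):
    """A peak-list file could not be parsed."""


class AmbiguityError(SlowexError, RuntimeError):
    """Peak-to-reference pairing admitted more than one assignment."""


class UndefinedPopulationError(SlowexError, ValueError):
    """Both state intensities are zero, so no population is defined."""


class DegenerateDataError(SlowexError, ValueError):
    """The data carry no information about the fitted parameter."""


class FitError(SlowexError, RuntimeError):
    """Least-squares fitting failed."""


class GenerationError(SlowexError, ValueError):
    """A synthetic-data specification would produce an untestable fixture."""
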