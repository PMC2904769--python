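"""Exception hierarchy for gaitgem.

Every error raised by the library derives from :class:`GaitgemError`, so
callers can catch the whole family with one clause.  Nonpositive stride
times or lengths are hard errors throughout: every downstream formula
divides by T or assumes forward progress.
"""


class GaitgemError(Exception):
    """Base class for all gaitgem errors."""


class InvalidSeriesError(GaitgemError, ValueError):
    """A stride series violates its invariants (lengths, positivity, belt)."""


class MalformedFileError(GaitgemError, ValueError):
    """A stride CSV is unreadable: missing columns, non-numeric or nonpositive values."""


class DegenerateSeriesError(GaitgemError, ValueError):
    """Zero-variance input where unit-variance normalization is requested."""


class TooShortSeriesError(GaitgemError, ValueError):
    """Series too short for the requested DFA box layout."""


class ConstantInputError(GaitgemError, ValueError):
    """DFA input is constant (fluctuation function would be zero)."""


class ConstraintUnsatisfiableError(GaitgemError, RuntimeError):
    """Surrogate rejection sampling exhausted its attempt budget."""


class NonpositiveStateError(GaitgemError, RuntimeError):
    """A simulated walker reached a nonpositive stride time or length."""
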