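"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`FldScreenError`, so pipeline
drivers can catch one type and report the failing stage.
"""


class FldScreenError(Exception):
    """Base class for all errors raised by fldscreen."""


class ConfigurationError(FldScreenError):
    """A configuration value violates its invariants (rates, ranges, counts)."""


class CalibrationError(FldScreenError):
    """The intercept root search could not reach the target prevalence."""


class EmptyCohortError(FldScreenError):
    """An operation that requires labelled rows received none."""


class StratificationError(FldScreenError):
    """A stratified split was requested but a class is absent or too small."""


class FitError(FldScreenError):
    """A fitting operation received degenerate input (e.g. no finite values)."""


class InputError(FldScreenError):
    """A value-level precondition failed (negative counts, non-finite input...)."""


class EvaluationError(FldScreenError):
    """An expression tree referenced an unknown feature or could not be applied."""


class TrainingError(FldScreenError):
    """The classifier could not be trained (e.g. single-class training data)."""
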