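"""Exception hierarchy for svml.

All domain errors derive from :class:`SvmlError` so callers (and the CLI)
can distinguish usage problems from internal failures.
"""


class SvmlError(Exception):
    """Base class for all svml domain errors."""


class ValidationError(SvmlError, ValueError):
    """An input value violates a documented precondition.

    The message names the offending field or argument.
    """


class TrainingError(SvmlError, RuntimeError):
    """Training cannot proceed (e.g. only one class effectively present)."""


class UndefinedMetricError(SvmlError, ValueError):
    """A metric's denominator is zero; the value is reported as missing,
    never silently coerced to 0."""


class FormatError(SvmlError, IOError):
    """A file is unreadable or not in a supported format."""
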