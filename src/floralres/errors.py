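"""Exception and warning types shared across the package.

The command-line layer maps these onto distinct exit codes so that a
malformed input file (:class:`SchemaError`) can be told apart from data
that are formally valid but insufficient for estimation
(:class:`EstimationError`).
"""


class FloralResError(Exception):
    """Base class for all package-specific errors."""


class InputError(FloralResError, ValueError):
    """A function argument violates its documented precondition."""


class LayoutError(InputError):
    """A sampling layout cannot be placed inside the plot geometry."""


class SchemaError(FloralResError):
    """A tabular input file does not match its documented schema."""


class EstimationError(FloralResError):
    """The data are insufficient to produce an estimate (e.g. fully censored)."""


class EstimationWarning(UserWarning):
    """An estimate was produced but is degenerate (e.g. zero with no detections)."""
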