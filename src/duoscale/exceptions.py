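"""Package-wide exception and warning types."""


class DuoscaleError(Exception):
    """Base class for all duoscale errors."""


class MonotonicityError(DuoscaleError):
    """Relative magnitudes are not monotone in the reference rank."""


class InfeasibleDesignError(DuoscaleError):
    """Requested schedule constraints cannot be satisfied simultaneously."""


class SchemaError(DuoscaleError):
    """A table or configuration does not conform to the expected schema."""


class ClampWarning(UserWarning):
    """A cursor position or rating was clamped to the scale boundary."""
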