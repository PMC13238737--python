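"""Exception and warning types shared across the package."""


class PairstairError(ValueError):
    """Invalid input or configuration detected by a pairstair routine."""


class DegenerateMetricWarning(UserWarning):
    """A metric denominator was degenerate; the value was set to 0."""


class BoundViolationWarning(UserWarning):
    """A pair's full-data MAE exceeded its cross-validated MAE."""
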