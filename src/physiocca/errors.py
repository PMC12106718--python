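"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a precondition (shape, range, or unit)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. a constant trace, or too few detectable breaths/beats)."""
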