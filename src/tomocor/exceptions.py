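"""Exception types shared across tomocor."""


class InvalidInputError(ValueError):
    """Input violates a documented precondition (shape, range, emptiness)."""


class DegenerateInputError(ValueError):
    """Input is formally valid but carries no usable signal.

    Examples: a constant image, a Fourier bin with zero magnitude.
    """


class ScanBoundaryError(RuntimeError):
    """A discrete search bottomed out at the edge of its scan range.

    The minimum found is not bracketed; rerun with a wider range.
    """
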