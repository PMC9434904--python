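"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An operation was called with arguments outside its contract."""


class NoColorMapFound(RuntimeError):
    """No colored (chromatic) pixel found inside the OCT scan window."""


class NoFAZFound(RuntimeError):
    """FAZ segmentation found no contour; the sample needs a manual crop."""


class StatsUndefined(ValueError):
    """Fewer than two observations: mean/covariance are undefined."""


class NumericalError(ArithmeticError):
    """A numerical routine left its validity envelope (e.g. non-PSD input)."""
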