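"""Exception types raised across the package."""


class TriangleError(ValueError):
    """A triangle template or trial violates triangle geometry."""


class MissingResponseError(ValueError):
    """An operation requiring a walked response met a trial without one."""


class UndefinedDirectionError(ValueError):
    """A zero-length response vector has no heading."""


class UndefinedCircularMeanError(ValueError):
    """Mean resultant length too small for a circular mean to exist."""


class DegenerateEncodingError(ValueError):
    """Encoded sides/angle fall outside the valid triangle range."""


class ParameterError(ValueError):
    """A model parameter is out of bounds or malformed."""


class FitFailureError(RuntimeError):
    """Every optimization start failed to converge."""
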