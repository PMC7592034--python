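"""Exception hierarchy shared by the delayepi modules."""


class DelayEpiError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DelayEpiError, ValueError):
    """A model or solver parameter violates its contract."""


class InvalidWindowError(DelayEpiError, ValueError):
    """A fit window contains nonpositive values or no grid points."""


class OutOfRegimeError(DelayEpiError, ValueError):
    """The requested quantity is undefined in this parameter regime
    (e.g. a positive growth exponent for R0 <= 1)."""


class ConvergenceError(DelayEpiError, RuntimeError):
    """The series has not settled within the integration horizon;
    extend the horizon and rerun."""


class ContractViolationError(DelayEpiError, RuntimeError):
    """An internal evaluation was requested outside the stored range."""
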