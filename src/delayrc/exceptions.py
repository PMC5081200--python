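"""Exception hierarchy for delayrc."""


class DelayRCError(Exception):
    """Base class for all delayrc errors."""


class ConfigurationError(DelayRCError, ValueError):
    """Invalid dimensions, schedules, parameter values or config keys."""


class SingularityError(DelayRCError, ArithmeticError):
    """The Mackey-Glass denominator 1 + X**rho fell below the guard.

    With the default parameters the denominator stays near 1; a trip
    indicates a misconfigured run (e.g. forcing far outside the intended
    range), so this is a hard error rather than a clipped value.
    """

    def __init__(self, t: float, value: float):
        self.t = t
        self.value = value
        super().__init__(
            f"Mackey-Glass nonlinearity singular at t={t:g}: "
            f"denominator magnitude {value:.3e} below guard"
        )


class RegressionDataError(DelayRCError, ValueError):
    """Empty or non-finite regression data."""


class UndefinedCorrelationError(DelayRCError, ValueError):
    """Pearson correlation requested for a zero-variance series."""
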