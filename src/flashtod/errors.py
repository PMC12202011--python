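"""Exception hierarchy shared across the package."""


class FlashTodError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FlashTodError, ValueError):
    """An input value lies outside the physical domain of an operation."""


class ValidationError(FlashTodError, ValueError):
    """A structured input (config, condition list, table) failed validation."""


class IntegrationError(FlashTodError, RuntimeError):
    """The ODE solver failed; carries the time reached before failure."""

    def __init__(self, message: str, time_reached: float):
        super().__init__(f"{message} (time reached: {time_reached:.6g} s)")
        self.time_reached = time_reached


class PipelineStageError(FlashTodError, RuntimeError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PairingError(FlashTodError, ValueError):
    """A comet record could not be matched to its control/CONV reference."""


class DegenerateReferenceError(FlashTodError, ZeroDivisionError):
    """CONV and control damage coincide; the damage ratio is undefined."""


class JoinError(FlashTodError, KeyError):
    """TOD/damage tables could not be joined one-to-one on condition keys."""


class DegenerateCorrelationError(FlashTodError, ValueError):
    """A correlation input column is constant; the statistic is undefined."""


class InfeasibleTargetError(FlashTodError, ValueError):
    """A scenario inversion target cannot be reached within the search bounds.

    Carries the best achievable OER change (percent) for diagnostics.
    """

    def __init__(self, message: str, best_change_percent: float):
        super().__init__(
            f"{message} (best achievable OER change: {best_change_percent:.4g}%)"
        )
        self.best_change_percent = best_change_percent
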