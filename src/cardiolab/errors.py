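"""Exception hierarchy for the simulator."""


class CardiolabError(Exception):
    """Base class for all package errors."""


class ValidationError(CardiolabError):
    """A user-facing parameter is outside its allowed closed interval."""

    def __init__(self, violations):
        # violations: list of (field, value, (lo, hi), unit)
        self.violations = list(violations)
        lines = [
            f"{field}={value!r} outside allowed range [{lo}, {hi}] {unit}"
            for field, value, (lo, hi), unit in self.violations
        ]
        super().__init__("; ".join(lines))


class ConfigError(CardiolabError):
    """A configuration file or coefficient table is malformed."""


class ModelError(CardiolabError):
    """A network builder was invoked with the wrong model selection."""


class TimingError(CardiolabError):
    """A mechanical trigger schedule does not fit inside the cycle."""


class StabilityError(CardiolabError):
    """The explicit update produced a negative volume; reduce the time step."""


class ConvergenceError(CardiolabError):
    """Steady state was not reached within the allowed number of cycles."""


class MetricsError(CardiolabError):
    """A trace does not contain a detectable complete cardiac cycle."""
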