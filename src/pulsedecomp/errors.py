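"""Exception hierarchy for the pulse-decomposition pipeline."""


class PulseDecompError(Exception):
    """Base class for all package errors."""


class ParameterError(PulseDecompError, ValueError):
    """A model or generator parameter violates its domain constraints."""


class InputError(PulseDecompError, ValueError):
    """An input signal or table is malformed or degenerate."""


class DetectionError(PulseDecompError, RuntimeError):
    """A feature detector found nothing usable in the signal."""


class SelectionError(PulseDecompError, RuntimeError):
    """No run of clean consecutive beats long enough for episode selection."""

    def __init__(self, message: str, longest_clean_run: int = 0):
        super().__init__(message)
        self.longest_clean_run = longest_clean_run


class FitError(PulseDecompError, RuntimeError):
    """The swarm optimizer could not produce a feasible fit."""


class DesignError(PulseDecompError, ValueError):
    """The factorial layout is rank-deficient (empty cells) or underspecified."""
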