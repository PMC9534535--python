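"""Exception hierarchy for numspike."""


class NumspikeError(Exception):
    """Base class for all numspike-specific errors."""


class PlacementError(NumspikeError, RuntimeError):
    """Raised when item placement fails after the bounded number of rejection attempts."""


class IdxFormatError(NumspikeError, ValueError):
    """Raised on malformed IDX files (bad magic, truncation, dimension mismatch)."""


class InvalidProbabilityError(NumspikeError, ValueError):
    """Raised when the encoder would require a per-step spike probability above 1."""


class MissingClassError(NumspikeError, ValueError):
    """Raised when a stimulus class expected in the trial set has no trials."""


class EmptyResultError(NumspikeError, ValueError):
    """Raised when an analysis step has no selective units to work with."""


class FitDegenerateError(NumspikeError, ValueError):
    """Raised when a tuning curve is constant and a Gaussian fit is meaningless."""


class MissingScaleError(NumspikeError, ValueError):
    """Raised when no converged fit exists on a requested abscissa scale."""


class ConfigError(NumspikeError, ValueError):
    """Raised on invalid experiment configuration; carries all violations at once."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
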