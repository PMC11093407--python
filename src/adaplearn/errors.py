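"""Exception hierarchy shared across the package."""


class AdaplearnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdaplearnError, ValueError):
    """A configuration field is invalid or makes the request infeasible."""


class DataError(AdaplearnError, ValueError):
    """Input data violate a precondition (wrong task, misaligned lengths, ...)."""


class DegenerateInputError(DataError):
    """Input is formally valid but degenerate (constant regressor, zero variance)."""


class ValidationError(DataError):
    """A session table failed schema validation; carries all failures at once."""

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__(
            "session table validation failed:\n" + "\n".join(self.failures)
        )


class StageError(AdaplearnError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
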