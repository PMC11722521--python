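"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data (shapes, values, empty selections)."""


class ConfigurationError(ValueError):
    """Mismatch between parameters/checkpoints and the requested model."""


class TrainingError(RuntimeError):
    """Training diverged or could not proceed; carries the loss log."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


class NumericalError(RuntimeError):
    """Numerical failure (non-finite values, ill-conditioned matrices)."""
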