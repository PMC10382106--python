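"""Exception hierarchy shared across the package."""


class PerinormError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PerinormError):
    """A configuration value is inconsistent or refers to unknown entities."""


class ParameterError(PerinormError):
    """Simulator parameters produce an invalid generative model."""


class InsufficientDataError(PerinormError):
    """Too few usable rows to fit or test."""


class DataIntegrityError(PerinormError):
    """Structural problem in an input table (duplicates, schema violation)."""


class ValidationError(PerinormError):
    """Row-level validation failures; carries per-row messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


class RangeError(PerinormError):
    """Covariates outside the permitted prediction range under strict mode."""


class CollinearityError(PerinormError):
    """Rank-transformed covariates are collinear or degenerate."""


class ConvergenceError(PerinormError):
    """Hyperparameter optimisation failed; carries best-so-far diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
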