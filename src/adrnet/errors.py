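"""Exception hierarchy shared across the package.

Three families matter to callers: user/configuration mistakes
(:class:`ConfigurationError`), problems with the input data
(:class:`DataError` and subclasses), and training failures
(:class:`TrainingDivergenceError`). The command-line layer maps these to
distinct exit codes.
"""


class AdrnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdrnetError):
    """Invalid configuration, hyperparameters, or mismatched shapes/schemas."""


class DataError(AdrnetError):
    """Base class for input-data problems."""


class ValidationError(DataError):
    """A dataset violates a structural invariant (duplicates, non-binary labels...)."""


class FeaturizationError(DataError):
    """A SMILES string could not be converted into a model input."""

    def __init__(self, message: str, smiles: str | None = None):
        super().__init__(message)
        self.smiles = smiles


class TrainingDivergenceError(AdrnetError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
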