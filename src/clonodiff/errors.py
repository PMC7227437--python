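"""Exception hierarchy shared across the package."""


class ClonodiffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ClonodiffError):
    """A clonotype table does not conform to the declared dialect."""


class ValidationError(ClonodiffError):
    """A value violates a domain invariant (e.g. negative UMI count)."""


class EmptyRepertoireError(ClonodiffError):
    """A clonotype table contains no data rows."""


class DepthError(ClonodiffError):
    """A requested sampling depth exceeds the available depth."""


class PairingError(ClonodiffError):
    """Two repertoires cannot be joined (e.g. chain mismatch)."""


class TrainingDataError(ClonodiffError):
    """Not enough clones to train the noise model."""


class FitError(ClonodiffError):
    """The dispersion optimizer failed to converge."""


class ChainError(ClonodiffError):
    """An operation was applied to the wrong receptor chain."""


class ConfigurationError(ClonodiffError):
    """A manifest or scenario configuration is invalid."""
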