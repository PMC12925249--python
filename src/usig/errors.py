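"""Exception and warning types used across the package."""


class UsigError(Exception):
    """Base class for all package-specific errors."""


class SignatureError(UsigError):
    """Problems with gene-signature definitions."""


class InvalidSignatureError(SignatureError):
    """Signature is empty or contains malformed tokens."""


class ConflictingSignError(SignatureError):
    """The same gene appears in both the positive and the negative set."""


class GmtFormatError(SignatureError):
    """Malformed GMT gene-set file."""


class ConfigurationError(UsigError):
    """Unknown policy tag or otherwise invalid configuration."""


class ParameterError(UsigError, ValueError):
    """Numeric parameter outside its valid domain."""


class UndefinedStatisticError(UsigError):
    """U statistic requested for an empty gene set (n = 0)."""


class FormatError(UsigError):
    """Malformed or inconsistent on-disk input."""


class DegenerateEmbeddingError(UsigError):
    """Embedding requested for a matrix with no variance."""


class SimulationSpecError(UsigError):
    """Infeasible synthetic-data specification."""


class UnscorableSignatureWarning(UserWarning):
    """A signature cannot be scored (e.g. all genes missing under skip policy)."""


class MissingGenesWarning(UserWarning):
    """Some signature genes were not found in the matrix gene universe."""
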