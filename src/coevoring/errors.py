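"""Exception types shared across the package."""


class CoevoringError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(CoevoringError):
    """Raised when an alignment file is malformed (e.g. ragged rows)."""


class ParameterError(CoevoringError, ValueError):
    """Raised when a user-supplied parameter is out of its valid range."""


class ConvergenceError(CoevoringError):
    """Raised when an iterative estimator fails to converge.

    Carries ``n_iter`` and ``duality_gap`` diagnostics when available.
    """

    def __init__(self, message: str, n_iter: int | None = None, duality_gap: float | None = None):
        super().__init__(message)
        self.n_iter = n_iter
        self.duality_gap = duality_gap


class StructureError(CoevoringError):
    """Raised for unusable atomic structures (no CA atoms, duplicate residues)."""


class MappingError(CoevoringError):
    """Raised when an alignment cannot be mapped onto a structure sequence."""
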