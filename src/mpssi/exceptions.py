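"""Exception hierarchy for mpssi."""


class MPSSIError(Exception):
    """Base class for all package-specific errors."""


class MalformedStateError(MPSSIError):
    """A state vector or MPS violates a structural precondition."""


class ShapeError(MPSSIError):
    """Operands have inconsistent dimensions."""


class ResourceLimitError(MPSSIError):
    """A dense expansion would exceed the configured size cap."""


class NearSingularOverlapError(MPSSIError):
    """An unpivoted triangular factorization hit a (near-)zero pivot."""

    def __init__(self, message: str, orbital: int | None = None):
        super().__init__(message)
        #: 1-based index of the orbital whose pivot failed, if known.
        self.orbital = orbital


class InvalidOverlapError(MPSSIError):
    """The AO overlap matrix is not symmetric positive definite."""


class SpinPurityError(MPSSIError):
    """A state is not the required spin eigenstate."""


class ConfigError(MPSSIError):
    """Invalid run configuration."""


class FileFormatError(MPSSIError):
    """A matrix or container file could not be parsed."""
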