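"""Exception hierarchy shared across the package."""


class PleiosimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PleiosimError, ValueError):
    """A simulation or test parameter is outside its valid range."""


class MatrixStructureError(PleiosimError, ValueError):
    """A matrix violates a structural requirement (symmetry, PSD, rank)."""


class SamplingError(PleiosimError, RuntimeError):
    """Rejection sampling exhausted its budget."""


class DegenerateInputError(PleiosimError, ValueError):
    """Data are degenerate for the requested operation (e.g. constant genotype)."""


class ConvergenceError(PleiosimError, RuntimeError):
    """An iterative fit failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class ConfigError(PleiosimError, ValueError):
    """A run configuration is invalid or incomplete."""
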