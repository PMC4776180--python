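"""Exception types raised across the package."""


class CatpopError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(CatpopError, ValueError):
    """A configuration or call parameter violates its contract."""


class InvalidInputError(CatpopError, ValueError):
    """A data argument (activity vector, drive vector, angle) is malformed."""


class UndefinedPeakError(CatpopError, ValueError):
    """Peak decoding requested on an all-zero activity profile."""


class SingularInformationError(CatpopError, ArithmeticError):
    """Fisher information undefined: zero mean rate with nonzero slope."""


class UnderflowError(CatpopError, ArithmeticError):
    """Filtering likelihood vanished everywhere despite log-domain arithmetic."""


class FitFailedError(CatpopError, RuntimeError):
    """Nonlinear least squares failed to converge from every start."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
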