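"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config = 2, data = 3, fit = 4).
"""


class SpinxesError(Exception):
    """Base class for all package errors."""


class ParameterError(SpinxesError, ValueError):
    """A model or lineshape parameter violates its contract."""


class ConfigError(SpinxesError, ValueError):
    """An experiment or fixture configuration is invalid."""


class GridError(SpinxesError, ValueError):
    """Energy grids of two spectra are incompatible."""


class TruncationError(SpinxesError, ValueError):
    """The energy grid does not cover a lineshape out to +/- 5 widths."""


class DataError(SpinxesError, ValueError):
    """Input data (shot stream, binned spectra, trace) is unusable."""


class FitError(SpinxesError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the last iterate in ``last_params`` when available.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DecompositionError(SpinxesError, ValueError):
    """Basis for a linear decomposition is rank deficient.

    ``condition_number`` holds the offending condition number.
    """

    def __init__(self, message, condition_number=None):
        super().__init__(message)
        self.condition_number = condition_number
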