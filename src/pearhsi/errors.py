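"""Exception hierarchy shared across the package."""


class PearHSIError(Exception):
    """Base class for all package errors."""


class ContractError(PearHSIError, ValueError):
    """An operation precondition was violated."""


class FormatError(PearHSIError, ValueError):
    """A file's declared structure does not match its contents."""


class GeometryError(PearHSIError, ValueError):
    """A layer/network geometry is inadmissible for the given input."""


class CalibrationError(PearHSIError, ValueError):
    """White/dark reference frames cannot define a reflectance transform."""


class DegenerateDistanceError(PearHSIError, ValueError):
    """All pairwise distances vanish; a normalized distance is undefined."""


class DivergenceError(PearHSIError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
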