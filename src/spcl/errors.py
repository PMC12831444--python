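"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`SPCLError`
so callers can catch package failures without masking programming errors.
"""


class SPCLError(Exception):
    """Base class for all package errors."""


class ParameterError(SPCLError, ValueError):
    """An argument violates an operation's precondition."""


class DataError(SPCLError, ValueError):
    """Input data cannot support the requested operation (e.g. missing class)."""


class BoundsError(SPCLError, ValueError):
    """A pixel box falls outside its image."""


class SamplingExhaustedError(SPCLError, RuntimeError):
    """Rejection sampling failed to find a qualifying draw within budget."""

    def __init__(self, mode: str, attempts: int, message: str | None = None):
        self.mode = mode
        self.attempts = attempts
        super().__init__(
            message
            or f"sampling exhausted in mode '{mode}' after {attempts} attempts"
        )


class DegenerateHistogramError(SPCLError, ValueError):
    """Otsu thresholding is undefined: the intensity histogram has one bin."""


class ManifestParseError(SPCLError, ValueError):
    """A manifest CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class StructureError(SPCLError, ValueError):
    """A batch or index structure violates the sample-positive construction."""


class ConfigurationError(SPCLError, ValueError):
    """Mutually inconsistent configuration (e.g. framework/branch mismatch)."""


class NumericalFailureError(SPCLError, RuntimeError):
    """Training produced a non-finite loss; carries the failing step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite loss at training step {step}")
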