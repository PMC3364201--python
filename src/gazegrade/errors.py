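"""Exception types shared across the pipeline."""


class GazegradeError(Exception):
    """Base class for all package errors."""


class InputError(GazegradeError, ValueError):
    """Malformed or inconsistent input data (raster shape mismatch, bad table)."""


class UndefinedAggregateError(GazegradeError, ValueError):
    """An aggregate (mean feature vector, delta) was requested over an empty set."""


class SingularFitError(GazegradeError, ValueError):
    """A regression could not be fitted (zero predictor variance)."""


class ValidationError(GazegradeError, ValueError):
    """Study-design validation failed (e.g. a missing condition partner)."""


class ParseError(GazegradeError, ValueError):
    """A delimited-text input file could not be parsed.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, lineno=None):
        self.path = path
        self.lineno = lineno
        if path is not None and lineno is not None:
            message = f"{path}:{lineno}: {message}"
        elif path is not None:
            message = f"{path}: {message}"
        super().__init__(message)
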