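"""Exception hierarchy for phenoprop."""


class PhenopropError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenopropError):
    """Invalid or infeasible configuration."""


class InputError(PhenopropError):
    """Invalid input data (empty file, mismatched node sets, ...)."""


class ParseError(InputError):
    """Malformed input row; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SeedError(InputError):
    """No usable seed genes remain after filtering."""


class NumericError(PhenopropError):
    """Numerical failure (non-convergence, degenerate vector)."""


class EvaluationError(PhenopropError):
    """Evaluation is undefined (e.g. no positive or no negative pairs)."""


class ModelError(PhenopropError):
    """Model cannot be fit or applied (e.g. no features selected)."""
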