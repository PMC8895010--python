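"""Exception hierarchy.

Every error raised by the library derives from :class:`MesoclusterError`
so callers can catch the package's failures with a single handler; the
subclasses distinguish bad arguments, underdetermined or degenerate fits,
optimizer failures (which carry the best iterate), and I/O schema problems.
"""


class MesoclusterError(Exception):
    """Base class for all library errors."""


class InvalidArgumentError(MesoclusterError, ValueError):
    """An argument violates a documented precondition (sign, ordering, range)."""


class UnderdeterminedFitError(MesoclusterError):
    """Fewer data points than free parameters."""


class DegenerateDataError(MesoclusterError):
    """Singular design matrix or otherwise uninformative data."""


class FitFailureError(MesoclusterError):
    """Optimizer did not converge; carries the best iterate found."""

    def __init__(self, message: str, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class ConfigError(MesoclusterError):
    """Invalid or incomplete pipeline configuration."""


class SchemaError(MesoclusterError):
    """Tabular input does not match the expected column schema."""
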