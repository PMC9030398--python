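"""Exception hierarchy shared across the package.

Each exception maps to a distinct CLI exit code so shell pipelines can
branch on the failure class (config 2, infeasible 3, non-convergence 4).
"""


class WristOptError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidParameterError(WristOptError, ValueError):
    """A physical or numerical parameter violates its contract."""

    exit_code = 2


class ConfigError(WristOptError, ValueError):
    """A run configuration, file schema, or fixture reference is invalid."""

    exit_code = 2


class TableSchemaError(ConfigError):
    """A muscle/ranges table violates the documented schema.

    Carries the offending row and column where known.
    """

    def __init__(self, message: str, row: object = None, column: object = None):
        parts = []
        if row is not None:
            parts.append(f"row {row!r}")
        if column is not None:
            parts.append(f"column {column!r}")
        detail = message if not parts else f"{message} ({', '.join(parts)})"
        super().__init__(detail)
        self.row = row
        self.column = column


class InfeasibleInstanceError(WristOptError, ValueError):
    """No non-negative force vector can satisfy moment equilibrium."""

    exit_code = 3


class SolverConvergenceError(WristOptError, RuntimeError):
    """An iterative solver failed to reach its tolerances."""

    exit_code = 4

    def __init__(self, message: str, status: str = ""):
        super().__init__(message if not status else f"{message} [status: {status}]")
        self.status = status
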