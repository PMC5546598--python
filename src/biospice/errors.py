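"""Exception hierarchy shared across the package."""

from __future__ import annotations


class BiospiceError(Exception):
    """Base class for all package errors."""


class FormatError(BiospiceError):
    """Malformed netlist input; carries the line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class CrossRefError(BiospiceError):
    """A reaction, directive or expression references an undeclared name."""


class CycleError(BiospiceError):
    """Cyclic parameter (or rule) dependencies."""

    def __init__(self, members):
        self.members = list(members)
        super().__init__(
            "cyclic definition involving: " + ", ".join(sorted(self.members))
        )


class ParameterError(BiospiceError):
    """Invalid or incomplete kinetic parameters for a reaction."""


class DomainError(BiospiceError):
    """A rate law was evaluated outside its domain (e.g. negative
    concentration)."""


class ConvergenceError(BiospiceError):
    """Steady-state search failed; carries the best residual reached."""

    def __init__(self, message: str, residual: float | None = None, state=None):
        if residual is not None:
            message = f"{message} (best residual {residual:.3e})"
        super().__init__(message)
        self.residual = residual
        self.state = state


class IntegrationError(BiospiceError):
    """Transient integration failed; carries the last good time."""

    def __init__(self, message: str, t_last: float | None = None):
        if t_last is not None:
            message = f"{message} (last good time {t_last:g})"
        super().__init__(message)
        self.t_last = t_last


class SbmlError(BiospiceError):
    """SBML document cannot be read or an unsupported construct was hit in
    strict mode."""


class SpiceDialectError(BiospiceError):
    """A construct cannot be expressed in the target simulator dialect."""
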