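"""Exception hierarchy."""


class EquilimbError(Exception):
    """Base class for all package errors."""


class GeometryError(EquilimbError):
    """Invalid or degenerate geometric input."""


class SchemaError(EquilimbError):
    """A geometry/loads file violates the documented schema."""


class InfeasibleError(EquilimbError):
    """The moment-balance system has no solution within the force bounds."""

    def __init__(self, message, residual=None, best_forces=None):
        super().__init__(message)
        self.residual = residual
        self.best_forces = best_forces


class ConvergenceError(EquilimbError):
    """The optimizer failed to converge; carries the best iterate."""

    def __init__(self, message, best_forces=None, diagnostics=None):
        super().__init__(message)
        self.best_forces = best_forces
        self.diagnostics = diagnostics
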