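"""Exception hierarchy shared across the package."""


class QmdffError(Exception):
    """Base class for package errors."""


class StructureError(QmdffError):
    """Mutually inconsistent topology / parameters / configuration sizes."""


class ConfigurationError(QmdffError):
    """Invalid simulation-cell or run configuration (e.g. box < 2 x cutoff)."""


class ParameterError(QmdffError):
    """Invalid user-supplied parameter value."""


class DegenerateGeometryError(QmdffError):
    """Geometry does not define the requested internal coordinate."""


class ConvergenceError(QmdffError):
    """Iterative procedure failed to converge."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class IntegrationBlowupError(QmdffError):
    """Non-finite forces or coordinates during integration."""

    def __init__(self, message: str, atom_index: int | None = None):
        super().__init__(message)
        self.atom_index = atom_index
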