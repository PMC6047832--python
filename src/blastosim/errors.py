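"""Exception hierarchy for blastosim."""


class BlastosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BlastosimError, ValueError):
    """Invalid user input (configuration, parameters, geometry)."""


class MeshError(ValidationError):
    """Invalid mesh construction parameters or degenerate mesh."""


class InvertedActiveMapError(BlastosimError):
    """The active deformation map is locally inverted (1 + k C X2 <= 0).

    Carries the biological cell id (if known) so the offending cell can be
    reported to the user.
    """

    def __init__(self, message, cell_id=None):
        super().__init__(message)
        self.cell_id = cell_id


class ElementInversionError(BlastosimError):
    """det F <= 0 at a quadrature point: the trial state is inadmissible.

    Carries the offending element indices and, when raised from the time
    loop, the step index.
    """

    def __init__(self, message, elements=None, step=None):
        super().__init__(message)
        self.elements = elements
        self.step = step


class UndefinedCorrelationError(BlastosimError):
    """Correlation requested between fields where at least one has zero variance."""
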