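"""Exception hierarchy shared across the package."""


class OdorintError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(OdorintError):
    """Fewer observations than free parameters of the requested curve family."""


class DegenerateGeometryError(OdorintError):
    """Point set has no 3-D extent (collinear or coplanar atoms)."""


class EmptyResultError(OdorintError):
    """An operation removed every column/row it was given."""


class MissingColumnError(OdorintError):
    """A required named column is absent from a table."""


class MissingParameterError(OdorintError):
    """A mixture component lacks the Hill parameters a model requires."""


class UnsupportedSizeError(OdorintError):
    """Mixture too large for combinatorial enumeration."""


class InfeasibleSplitError(OdorintError):
    """No clean component-disjoint train/test split exists."""

    def __init__(self, message: str, blocking_components=()):
        super().__init__(message)
        self.blocking_components = tuple(blocking_components)


class TrainingDivergedError(OdorintError):
    """Loss became non-finite during network training."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
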