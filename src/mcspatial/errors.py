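"""Exception hierarchy for mcspatial."""


class McSpatialError(Exception):
    """Base class for all package errors."""


class FormatError(McSpatialError):
    """A file does not conform to the documented table/region format."""


class EmptySourceError(McSpatialError):
    """An interaction query was issued for a sample with zero source cells.

    Distinct from the zero-target case, which yields +inf distances.
    """


class CouplingInfeasibleError(McSpatialError):
    """A simulation config requests distance coupling that cannot be realized.

    Raised when the coupled-partner count would exceed the phenotype's total
    partner budget, or when chance colocalization at the configured partner
    density already exceeds the coupling target.
    """


class GridMismatchError(McSpatialError):
    """Two hex-map layers were combined but live on different grids."""


class StageError(McSpatialError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
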