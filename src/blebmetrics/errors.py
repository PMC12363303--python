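"""Exception hierarchy for analysis failures.

Each failure mode the analysis can hit on real or synthetic data gets its
own class so callers (and the pipeline, which records per-replicate
failures without aborting an arm) can distinguish them.
"""


class BlebmetricsError(Exception):
    """Base class for all package-specific failures."""


class GeometryError(BlebmetricsError):
    """A phantom ingredient (bleb, cap) does not fit inside the grid."""


class SeedOutsideBlebError(BlebmetricsError):
    """Segmentation seed voxel lies below the threshold."""


class NoBlebFoundError(BlebmetricsError):
    """No voxel reaches the segmentation threshold."""


class TraceFormatError(BlebmetricsError):
    """A pressure-trace file violates the expected format; carries row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class FitError(BlebmetricsError):
    """Nonlinear fit failed; ``best`` carries the best candidate found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class AnalysisError(BlebmetricsError):
    """Generic analysis precondition violation (empty mask, empty window...)."""
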