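"""Exception hierarchy.

Validation errors (bad configuration or malformed inputs) are kept separate
from computation errors (a well-formed run that cannot produce a result) so
the command-line layer can map them to distinct exit codes.
"""


class LumpanelError(Exception):
    """Base class for all package errors."""


class ValidationError(LumpanelError):
    """Malformed input, configuration, or schema mismatch."""


class ComputationError(LumpanelError):
    """A well-formed request whose result is undefined or inestimable."""


class CRSError(ValidationError):
    """Mixed, missing, or geographic (degree-based) coordinate systems."""


class UnlocatableResidenceError(ComputationError):
    """Residence point farther from the road network than the snap tolerance."""

    def __init__(self, distance_m: float, max_snap_m: float):
        self.distance_m = float(distance_m)
        self.max_snap_m = float(max_snap_m)
        super().__init__(
            f"unlocatable residence: nearest road edge is {distance_m:.1f} m away "
            f"(snap tolerance {max_snap_m:.1f} m)"
        )


class NoCoverageError(ComputationError):
    """Buffer has zero land-use coverage in the exposure year."""


class InestimableError(ComputationError):
    """Model term cannot be estimated (e.g. zero within-person variance)."""
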