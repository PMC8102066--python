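"""Exception hierarchy shared across the package."""


class DimerlensError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(DimerlensError):
    """Invalid topology definition (overlapping domains, orphan beads...)."""


class TrajectoryError(DimerlensError):
    """Invalid or corrupt coordinate data."""


class EstimationError(DimerlensError):
    """Statistical estimation cannot proceed (disconnected data, bad lag...)."""


class AnalysisError(DimerlensError):
    """Invalid analysis request (bad cutoffs, empty subsets, bad calibration...)."""
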