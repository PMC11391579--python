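"""Exception hierarchy for flexbench.

All package-specific failures derive from :class:`FlexbenchError` so callers
can distinguish scientific/data problems from programming errors.
"""


class FlexbenchError(Exception):
    """Base class for all flexbench errors."""


class PDBParseError(FlexbenchError):
    """PDB text could not be interpreted (no CA atoms, insertion codes, ...)."""


class EnsembleConsistencyError(FlexbenchError):
    """Models of a multi-model file do not share the same residue set."""


class DimensionError(FlexbenchError):
    """Mismatched array lengths between paired inputs."""


class DegenerateGeometryError(FlexbenchError):
    """Geometry unsuitable for the requested operation (too few or coincident points)."""


class InsufficientDataError(FlexbenchError):
    """Not enough models/observations for a statistical estimate."""


class DisconnectedNetworkError(FlexbenchError):
    """Elastic network has more than six zero modes (independent rigid bodies)."""


class ZeroModeCountError(FlexbenchError):
    """Fewer than six near-zero modes found; numerical tolerance problem."""


class MissingDataError(FlexbenchError):
    """Required column (e.g. B-factors) absent from the input."""


class TruncationDegenerateError(FlexbenchError):
    """Terminal truncation would remove the entire chain."""


class NormalizationError(FlexbenchError):
    """Profile cannot be normalized (all values zero)."""


class AlignmentError(FlexbenchError):
    """Residue numbering of two profiles/ensembles does not match."""


class UndefinedStatisticError(FlexbenchError):
    """Statistic undefined for the input (zero variance, all ties, ...)."""


class DesignError(FlexbenchError):
    """ANOVA design invalid or degenerate (empty level, zero residual df)."""
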