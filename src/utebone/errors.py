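"""Exception hierarchy shared by all utebone modules."""


class UteBoneError(Exception):
    """Base class for all utebone-specific errors."""


class FormatError(UteBoneError):
    """A file was readable but its content is not what was expected
    (e.g. 4D data where a scalar 3D volume is required)."""


class GeometryError(UteBoneError):
    """Voxel-grid or affine problem: mismatched grids, non-invertible
    affine, degenerate phantom geometry."""


class EstimationError(UteBoneError):
    """A data-driven estimate (background statistics, soft-tissue peak)
    could not be computed from the given volume."""


class ConfigurationError(UteBoneError):
    """Inconsistent configuration, e.g. mismatched histogram binnings."""


class ContractError(UteBoneError):
    """API misuse: an operation was called on an object in the wrong
    state (e.g. applying prior constraints twice)."""


class StatisticsError(UteBoneError):
    """Degenerate input to a statistical test."""
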