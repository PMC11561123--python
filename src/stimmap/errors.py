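"""Exception hierarchy shared across the pipeline."""


class StimMapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StimMapError):
    """A file could not be parsed as the expected on-disk format."""


class SchemaError(StimMapError):
    """A table is missing mandatory columns or violates its declared schema."""


class GridMismatchError(StimMapError):
    """Two volumes that must share a voxel grid do not."""


class UnitError(StimMapError):
    """An unrecognized physical unit tag."""


class InputError(StimMapError):
    """Inputs are structurally valid but unusable (empty cohort, too few patients...)."""


class StateError(StimMapError):
    """An operation was called on an object missing required derived state."""


class ConfigError(StimMapError):
    """A generator or run configuration is invalid."""
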