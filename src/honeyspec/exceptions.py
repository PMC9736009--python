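"""Exception hierarchy.

All honeyspec errors derive from :class:`HoneyspecError` so callers can
catch the package's failures with a single except clause; each subclass
additionally derives from the closest builtin (ValueError / KeyError) so
generic numeric code keeps working.
"""


class HoneyspecError(Exception):
    """Base class for all honeyspec errors."""


class ConfigurationError(HoneyspecError, ValueError):
    """A configuration value is invalid or an invariant cannot be met."""


class DomainError(HoneyspecError, ValueError):
    """An argument lies outside its mathematical domain (e.g. fraction > 100)."""


class DimensionError(HoneyspecError, ValueError):
    """Array extents are inconsistent (ROI bounds, tiling divisibility...)."""


class DivisionDomainError(HoneyspecError, ValueError):
    """A white-reference value is non-positive where a ratio is required."""


class LookupMaterialError(HoneyspecError, KeyError):
    """A material name is not present in the endmember library."""


class SamplingError(HoneyspecError, ValueError):
    """A class has too few members for the requested subsample."""


class StratificationError(HoneyspecError, ValueError):
    """A class has fewer members than the number of folds."""


class LabelError(HoneyspecError, ValueError):
    """A prediction label is absent from the declared class order."""


class StageError(HoneyspecError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
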