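"""Exception hierarchy used across the pipeline.

Degenerate inputs fail loudly rather than propagating NaN.
"""


class NavdynError(Exception):
    """Base class for all navdyn errors."""


class InvalidConfigError(NavdynError):
    """Configuration value outside its valid range, or unknown key."""


class SchemaError(NavdynError):
    """A table or array does not match the documented schema."""


class DegenerateSignalError(NavdynError):
    """Zero-mean or zero-variance signal where a ratio or correlation is needed."""


class AlignmentError(NavdynError):
    """Event timing does not align with the acquisition frame grid."""


class StageDependencyError(NavdynError):
    """A pipeline stage was run before its upstream outputs exist."""
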