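"""Exception hierarchy for bloodspec.

Every error raised by the package derives from :class:`BloodspecError` so
callers can catch pipeline failures without masking programming errors.
"""


class BloodspecError(Exception):
    """Base class for all bloodspec errors."""


class FormatError(BloodspecError):
    """A file or table does not match the expected layout or enumerations."""


class AxisError(BloodspecError):
    """Wavenumber axis is non-monotone, non-uniform or inconsistent."""


class DuplicateRecordError(BloodspecError):
    """Two spectra share the same (subject, biofluid, spot, replicate)."""


class RegionError(BloodspecError):
    """A requested wavenumber interval does not intersect the axis."""


class DegenerateInputError(BloodspecError):
    """An input is degenerate for the operation (e.g. all-zero spectrum)."""


class ParameterError(BloodspecError):
    """A numeric parameter violates the operation's preconditions."""


class CVDesignError(BloodspecError):
    """A cross-validation design is infeasible (e.g. single-subject class)."""


class LeakageError(BloodspecError):
    """Train and test sets share a subject."""


class DesignError(BloodspecError):
    """Inconsistent analysis design (mismatched axes, unknown labels...)."""


class ConfigError(BloodspecError):
    """Invalid simulation or run configuration."""


class SchemaError(BloodspecError):
    """Report schema version mismatch."""
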