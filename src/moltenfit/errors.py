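"""Exception hierarchy.

Every error raised by moltenfit derives from :class:`MoltenfitError` so
callers can catch the package's failures with a single except clause.
"""


class MoltenfitError(Exception):
    """Base class for all moltenfit errors."""


class FormatError(MoltenfitError):
    """A delimited input file violates the expected layout."""


class ValidationError(MoltenfitError):
    """Input data violates a container invariant (e.g. unknown residue)."""


class ParameterError(MoltenfitError):
    """A user-supplied parameter is outside its admissible range."""


class FitError(MoltenfitError):
    """A nonlinear fit failed to converge or produced an inadmissible model."""


class AlignmentError(MoltenfitError):
    """Two series that must share a grid do not."""


class RangeError(MoltenfitError):
    """A requested evaluation point lies outside the data coverage."""


class ComparabilityError(MoltenfitError):
    """Two datasets cannot be compared (e.g. quencher ranges barely overlap)."""


class ConfigurationError(MoltenfitError):
    """A run configuration or manifest entry is invalid."""


class DataError(MoltenfitError):
    """Data are structurally valid but unusable (e.g. all channels masked)."""
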