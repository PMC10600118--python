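"""Exception hierarchy.

Parameter errors are user-input problems (bad probabilities, unknown nuclease);
data errors arise from sequences that violate a geometric or uniqueness
precondition. The CLI maps the two branches onto distinct exit codes.
"""


class DelinverError(Exception):
    """Base class for all package errors."""


class ParameterError(DelinverError, ValueError):
    """Invalid configuration or argument value."""


class PlacementError(DelinverError):
    """A guide target cannot be placed at the requested position."""


class TargetNotFoundError(DelinverError):
    """Protospacer+PAM has no exact match in the locus."""


class AmbiguousTargetError(DelinverError):
    """Protospacer matches more than one site (multiplex safety check)."""


class GeometryError(DelinverError):
    """Cut-site arithmetic is inconsistent (overlapping windows, out of range)."""


class DesignError(DelinverError):
    """No valid primer scheme exists under the given constraints."""


class DesignInfeasibleError(DesignError):
    """The wild-type segment is short enough to amplify in tier 1."""


class ZeroVarianceError(DelinverError):
    """Correlation requested on a constant vector."""
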