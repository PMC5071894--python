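"""Exception hierarchy.

Every failure surfaced by the library maps onto one of a small set of
categories (config, format, geometry, discretization, validation,
convergence, numeric, io) so that the CLI can exit with a categorized
message.
"""


class AeroscatterError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(AeroscatterError):
    """A file could not be parsed in the declared dialect."""

    category = "format"


class GeometryError(AeroscatterError):
    """Invalid or inconsistent geometric input (non-watertight mesh, bad mirror plane, ...)."""

    category = "geometry"


class DiscretizationError(AeroscatterError):
    """A lattice spacing is unusable (too coarse to yield any sites, ...)."""

    category = "discretization"


class ValidationError(AeroscatterError):
    """Arguments violate a documented precondition."""

    category = "validation"


class ConvergenceError(AeroscatterError):
    """The iterative solver failed to reach the requested residual."""

    category = "convergence"

    def __init__(self, message, residual=None, iterations=None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class NumericError(AeroscatterError):
    """A numerically degenerate input (e.g. a polarizability pole)."""

    category = "numeric"


class MaterialLookupError(AeroscatterError, KeyError):
    """Unknown material name."""

    category = "validation"
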