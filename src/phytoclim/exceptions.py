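"""Exception hierarchy shared across the pipeline."""


class PhytoclimError(Exception):
    """Base class for all package errors."""


class FormatError(PhytoclimError, ValueError):
    """A file does not match the declared raster/tabular layout."""


class ValidationError(PhytoclimError, ValueError):
    """Data violate a type invariant (e.g. tmin > tmax, wp > fc)."""


class EmptyPoolError(PhytoclimError, ValueError):
    """An operation needs at least one unmasked (land) cell and got none."""


class ConvergenceError(PhytoclimError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class DegenerateSampleError(PhytoclimError, ValueError):
    """A presence/absence sample cannot support model fitting."""
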