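"""Exception hierarchy shared across the package."""


class RadbiodoseError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedNuclideError(RadbiodoseError, KeyError):
    """Requested nuclide is not in the embedded decay table."""


class DomainError(RadbiodoseError, ValueError):
    """A numeric argument is outside its physical domain."""


class GeometryError(RadbiodoseError, ValueError):
    """A point or region is inconsistent with the cylindrical assembly."""


class ParameterError(RadbiodoseError, ValueError):
    """A generator or model parameter combination is infeasible."""


class InsufficientDataError(RadbiodoseError, ValueError):
    """Too few data points for the requested fit or summary."""


class DegenerateThresholdError(RadbiodoseError, ValueError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class NoCellsError(RadbiodoseError, ValueError):
    """No nuclear area present; an area ratio is undefined."""


class SchemaError(RadbiodoseError, ValueError):
    """A tabular input does not match the expected column schema."""
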