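"""Exception taxonomy shared by all pipeline stages."""


class EstrocycleError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(EstrocycleError, ValueError):
    """A caller-supplied parameter violates its contract."""


class DataError(EstrocycleError, ValueError):
    """Input data violate a structural precondition (unsorted, too short...)."""


class DegenerateDataError(DataError):
    """Data are structurally valid but degenerate for the requested operation
    (zero variance, constant regressor, empty reference epoch...)."""
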