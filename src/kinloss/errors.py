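"""Exception hierarchy for the kinloss pipeline.

Validation errors (schema, duplication, configuration) indicate malformed
inputs and are distinguished from estimation errors, which indicate that
inputs are well-formed but insufficient for the requested computation.
"""


class KinlossError(Exception):
    """Base class for all kinloss errors."""


class SchemaError(KinlossError):
    """A table does not conform to its declared schema."""


class DuplicateStratumError(SchemaError):
    """Two rows share the same stratum key; never silently summed."""


class ConfigurationError(KinlossError):
    """A configuration table or parameter is invalid."""


class EstimationError(KinlossError):
    """Inputs are valid but insufficient or inconsistent for estimation."""


class AlignmentError(EstimationError):
    """Two tables that must share strata do not align."""


class IntegrityError(KinlossError):
    """A line list contains dangling or inconsistent links."""
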