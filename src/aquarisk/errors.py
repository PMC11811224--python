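"""Exception hierarchy.

The CLI maps these onto exit codes: validation/configuration problems -> 2,
data/schema problems -> 3, numerical problems (fitting, sampling) -> 4.
"""


class AquariskError(Exception):
    """Base class for all package errors."""


class ValidationError(AquariskError, ValueError):
    """An input value or combination of values violates a documented contract."""


class ConfigurationError(AquariskError, ValueError):
    """A configuration object (contaminant spec, profile, distribution) is unusable."""


class EmptyInputError(ValidationError):
    """An operation that requires data received an empty collection."""


class SchemaError(AquariskError, ValueError):
    """A delimited file does not have the required columns."""


class DataError(AquariskError, ValueError):
    """A delimited file has the right shape but unusable content."""


class FittingError(AquariskError, ValueError):
    """Distribution fitting is impossible on the given values."""


class SamplingError(AquariskError, RuntimeError):
    """Random sampling cannot proceed (e.g. truncation region with negligible mass)."""


class DegenerateInputError(AquariskError, ValueError):
    """Every candidate input to a sensitivity analysis is constant."""


class FixtureLookupError(AquariskError, KeyError):
    """An unknown built-in fixture name was requested."""
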