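"""Exception hierarchy for the coamscreen pipeline.

Every error raised on a contract violation derives from :class:`CoamError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class CoamError(Exception):
    """Base class for all coamscreen errors."""


class SchemaError(CoamError):
    """A table is missing a mandatory column or has an unusable header."""


class TableParseError(CoamError):
    """A cell could not be parsed; message names the offending row."""


class ValidationError(CoamError):
    """Record-level constraint violated (duplicate name, dangling reference...)."""


class StructureError(CoamError):
    """A molecular structure (SMILES/SDF) could not be interpreted."""


class DescriptorError(CoamError):
    """A required descriptor field is absent or out of domain."""


class DomainError(CoamError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateFeatureError(CoamError):
    """A feature column has zero variance and cannot be autoscaled."""


class DegenerateTrainingError(CoamError):
    """Training response contains a single class."""


class ConvergenceError(CoamError):
    """NIPALS failed to extract a latent variable."""


class ContractError(CoamError):
    """Caller violated an interface contract (length/order mismatch)."""


class DimensionalityError(CoamError):
    """An operation needs more latent variables than the model has."""


class EvaluationError(CoamError):
    """A screen cannot be scored (e.g. unknown experimental outcome)."""


class ConfigError(CoamError):
    """A synthetic-data or run configuration is invalid."""
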