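"""Exception hierarchy shared across the pipeline."""


class LarvaphenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(LarvaphenError):
    """An input table does not expose a required column."""


class DataError(LarvaphenError):
    """Input values violate a data contract (negative distance,
    non-monotone time, trace/regime mismatch, ...)."""


class ConfigError(LarvaphenError):
    """A schedule or run configuration is internally inconsistent."""
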