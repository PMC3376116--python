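"""Exception hierarchy."""


class SelsvmError(Exception):
    """Base class for all package errors."""


class SchemaError(SelsvmError):
    """Malformed input table or column mapping."""


class DatasetError(SelsvmError):
    """A labeled dataset cannot be constructed as requested."""


class ModelError(SelsvmError):
    """Training, prediction, or persistence failure."""


class ConfigError(SelsvmError):
    """Invalid run configuration."""
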