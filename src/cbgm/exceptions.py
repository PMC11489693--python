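"""Exception hierarchy."""


class CbgmError(Exception):
    """Base class for package errors."""


class FormatError(CbgmError):
    """A file does not conform to the expected on-disk format."""


class LeadNotFoundError(CbgmError):
    """A requested ECG lead is not present in the record."""


class SchemaError(CbgmError):
    """A segment dataset file has a malformed schema or truncated rows."""


class ConfigError(CbgmError):
    """An invalid configuration value."""


class TrainingError(CbgmError):
    """Training diverged or could not proceed."""
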