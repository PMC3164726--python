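"""Exception hierarchy shared across the pipeline stages."""


class DockTriageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DockTriageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(DockTriageError, ValueError):
    """Malformed or inconsistent input data."""
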