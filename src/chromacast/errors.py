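"""Exception hierarchy.

``DataError`` marks malformed or inconsistent input data (exit code 3 in the
CLI); ``ConfigError`` marks an unusable run configuration (exit code 2).
"""


class ChromacastError(Exception):
    """Base class for all package-specific errors."""


class DataError(ChromacastError):
    """Malformed, inconsistent or unreadable input data."""


class ConfigError(ChromacastError):
    """Invalid run or model configuration."""
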