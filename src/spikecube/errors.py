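"""Exceptions shared across the package and mapped to CLI exit codes."""


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataFormatError(Exception):
    """Malformed or missing input data (CLI exit code 3)."""
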