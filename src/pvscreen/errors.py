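"""Exception hierarchy mapped onto CLI exit codes."""


class PvscreenError(Exception):
    """Base class for package errors. CLI exit code 4."""

    exit_code = 4


class ConfigError(PvscreenError):
    """Invalid configuration or missing input file. CLI exit code 2."""

    exit_code = 2


class DataError(PvscreenError):
    """Malformed or inconsistent input data. CLI exit code 3."""

    exit_code = 3
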