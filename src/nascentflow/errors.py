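"""Exception hierarchy mapped onto CLI exit codes."""


class NascentflowError(Exception):
    """Base class; `exit_code` is what the CLI returns on failure."""

    exit_code = 1


class ConfigurationError(NascentflowError):
    """Invalid parameters, thresholds, or experimental design."""

    exit_code = 2


class InputFormatError(NascentflowError):
    """Malformed or unreadable input data."""

    exit_code = 3


class DegenerateDataError(NascentflowError):
    """Statistically degenerate input (e.g. zero normalization denominator)."""

    exit_code = 4
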