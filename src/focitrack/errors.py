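"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class FociTrackError(Exception):
    """Base class for all focitrack errors."""


class ConfigError(FociTrackError):
    """Invalid configuration, parameter out of domain, or insufficient table range."""


class DataError(FociTrackError):
    """Malformed or inconsistent input data (files, histograms, records)."""


class NumericalError(FociTrackError):
    """A fit or numerical procedure failed to produce a usable result."""
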