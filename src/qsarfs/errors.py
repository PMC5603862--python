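"""Exception hierarchy shared by all qsarfs modules."""


class QsarfsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QsarfsError):
    """A parameter, option, or config file value is invalid."""


class DataError(QsarfsError):
    """Input data violates a contract (shape, type, missing value, domain)."""


class NumericalError(QsarfsError):
    """A linear solve or other numerical routine failed."""
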