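"""Exception hierarchy shared across the package."""


class QocError(Exception):
    """Base class for package errors."""


class ConfigError(QocError):
    """Invalid configuration; the message names the offending field."""


class DataIntegrityError(QocError):
    """Input records violate a schema or ordering invariant."""


class EstimationError(QocError):
    """A model could not be estimated from the data provided."""
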