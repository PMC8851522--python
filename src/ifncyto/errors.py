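"""Exception hierarchy shared across the package.

DataError covers malformed or empty inputs (exit code 1 in the CLI);
ConfigError covers schema/parameter problems detected before compute
(exit code 2).
"""


class IfnCytoError(Exception):
    """Base class for package errors."""


class DataError(IfnCytoError):
    """Input data is malformed, empty, or out of range."""


class SchemaError(DataError):
    """A required column/gene/channel is missing or duplicated."""


class ConfigError(IfnCytoError):
    """Invalid parameter or configuration, detected before compute."""


class StateError(IfnCytoError):
    """Operation applied to data in the wrong transform state."""


class FitError(IfnCytoError):
    """Model could not be estimated (rank deficiency, degenerate response)."""
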