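"""Exception hierarchy.

``ParknetError`` is the base; the CLI maps :class:`InputError` (bad user
input, exit code 1) and anything else (exit code 2) onto exit codes.
"""


class ParknetError(Exception):
    """Base class for all package errors."""


class InputError(ParknetError):
    """Invalid user-supplied data (bad matrix, mismatched gene universes...)."""


class ConfigError(InputError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(InputError):
    """A table failed schema validation; message names file/column/row."""
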