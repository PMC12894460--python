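"""Exception hierarchy for the package.

Exit-code mapping used by the CLI: ValidationError and ConfigError are
user-input problems (exit 2 in the CLI is reserved for runtime errors,
1 for validation — see cli.py).
"""


class CfdnaAncestryError(Exception):
    """Base class for all package errors."""


class ValidationError(CfdnaAncestryError):
    """Input values violate a documented precondition."""


class FormatError(CfdnaAncestryError):
    """A file does not conform to its expected dialect."""


class ConfigError(CfdnaAncestryError):
    """A configuration value or file is invalid."""
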