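"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`SchemaError` and :class:`ContractError`
exit with code 2, :class:`InsufficientDataError` with code 3.
"""


class RefstabError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RefstabError):
    """Input file or table does not match the expected schema."""


class IntegrityError(SchemaError):
    """Input violates a uniqueness or consistency constraint."""


class ContractError(RefstabError):
    """Arguments violate an operation's contract (caller bug)."""


class InsufficientDataError(RefstabError):
    """Too few observations to compute the requested statistic."""


class DomainError(RefstabError, ValueError):
    """A numeric parameter is outside its valid domain."""
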