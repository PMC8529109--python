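"""Exception hierarchy shared across the package."""


class FuncstabError(Exception):
    """Base class for all package-specific errors."""


class ProfileFormatError(FuncstabError):
    """A profile file is structurally malformed (e.g. a required column is missing)."""


class ProfileValidationError(FuncstabError):
    """A profile file parsed but violates a content invariant (e.g. negative hits)."""


class ContractError(FuncstabError):
    """An operation was called on data that violates its precondition."""
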