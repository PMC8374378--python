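"""Exception hierarchy shared across the package."""


class CareHomeLinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CareHomeLinkError, ValueError):
    """A configuration value is out of range or inconsistent; the message names the field."""


class GenerationError(CareHomeLinkError):
    """The synthetic generator was asked for something impossible (e.g. residents without homes)."""


class CodelistError(CareHomeLinkError, ValueError):
    """A codelist file is empty, malformed or contains duplicate codes."""


class SchemaError(CareHomeLinkError, ValueError):
    """An input table is missing a required column; the message names table and column."""


class DataIntegrityError(CareHomeLinkError, ValueError):
    """A foreign key does not resolve; the message lists the offending ids."""


class EmptyFlagSetError(CareHomeLinkError, ZeroDivisionError):
    """A percentage was requested over an empty flagged set."""
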