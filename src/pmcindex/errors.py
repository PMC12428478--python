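"""Exception types raised across the package."""


class PMCError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PMCError):
    """The variable schema is malformed (duplicate ids, empty scored primary, ...)."""


class CodingError(PMCError):
    """A coding matrix violates the binary-cell contract or the schema."""


class MetadataError(PMCError):
    """Policy metadata is missing or unparseable (bad date, duplicate code)."""
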