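"""Exception hierarchy shared across the toolkit."""


class KGError(Exception):
    """Base class for all toolkit errors."""


class ParseError(KGError):
    """A file could not be parsed; message names the offending line."""


class SchemaViolationError(KGError):
    """A triple or schema element violates the ontology schema."""


class UsageError(KGError):
    """An operation was called with arguments outside its contract."""


class EntityLookupError(KGError, KeyError):
    """An entity or relation id was not found in the graph."""


class GenerationError(KGError):
    """The synthetic generator could not satisfy its configuration."""
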