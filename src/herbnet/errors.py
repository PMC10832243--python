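"""Exception hierarchy shared across the pipeline stages."""


class HerbnetError(Exception):
    """Base class for all package-specific failures."""


class SchemaError(HerbnetError):
    """An input table is missing a mandatory column or field."""


class DialectError(HerbnetError):
    """A score lies outside the declared scale, or the scale is unknown."""


class FormatError(HerbnetError):
    """An unknown or unsupported serialization format was requested."""


class StageError(HerbnetError):
    """A pipeline stage received input it cannot process (e.g. empty core set)."""
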