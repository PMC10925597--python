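"""Exception hierarchy for the liqbio pipeline."""


class LiqbioError(Exception):
    """Base class for all liqbio errors."""


class ValidationError(LiqbioError):
    """A domain object violates one of its invariants."""


class SchemaError(LiqbioError):
    """An input file does not match the declared schema."""


class ConfigError(LiqbioError):
    """A configuration object is internally inconsistent."""


class StratificationError(LiqbioError):
    """A stratified split or fold assignment is impossible for the given data."""
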