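"""Exception hierarchy for toxpimap."""


class ToxpimapError(Exception):
    """Base class for all toxpimap errors."""


class ConfigurationError(ToxpimapError):
    """Invalid model definition, missing columns, bad parameter combinations."""


class ParseError(ToxpimapError):
    """Unparseable input data (carries row/column context in the message)."""


class ValidationError(ToxpimapError):
    """Data violates a documented invariant (range, uniqueness, schema)."""


class CRSError(ToxpimapError):
    """Unknown or unusable coordinate reference system."""
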