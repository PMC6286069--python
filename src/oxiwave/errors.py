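"""Exception types raised by the oxiwave pipeline."""


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


class QualityError(ValueError):
    """A recording failed a signal-quality gate (e.g. too many artifacts)."""


class TooShortError(ValueError):
    """A recording or segment is shorter than an operation requires."""
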