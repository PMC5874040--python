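"""Exception hierarchy for the alignment pipeline."""


class EmbryoAlignError(Exception):
    """Base class for all pipeline errors."""


class ParseError(EmbryoAlignError):
    """A file could not be parsed (malformed row, bad header, empty stack)."""


class ValidationError(EmbryoAlignError):
    """An input violates a documented invariant (e.g. a center outside the frame)."""


class GeometryError(EmbryoAlignError):
    """Degenerate geometry: coplanar hull input, non-solid moments, bad scale factors."""


class AmbiguityError(EmbryoAlignError):
    """The requested quantity is not uniquely determined (ties, degenerate configurations)."""


class PipelineError(EmbryoAlignError):
    """A pipeline stage failed hard (missing inputs, no viable offset, ...)."""
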