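"""Exception hierarchy."""


class PollenMorphError(Exception):
    """Base class for all package errors."""


class ProfileError(PollenMorphError):
    """Invalid taxon profile field."""


class ContourError(PollenMorphError):
    """Contour construction or validation failure."""


class FeatureError(PollenMorphError):
    """Feature extraction failure (bad contour, empty mask, ...)."""


class SchemaError(PollenMorphError):
    """Tabular input does not match the frozen feature schema."""


class PipelineError(PollenMorphError):
    """A pipeline stage failed; the message names the stage."""
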