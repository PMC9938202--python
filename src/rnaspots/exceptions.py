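"""Package-level exception types."""


class RnaspotsError(Exception):
    """Base class for rnaspots errors."""


class PlacementError(RnaspotsError):
    """Synthetic nuclei could not be placed (field too crowded)."""


class ConfigurationError(RnaspotsError):
    """Invalid or inconsistent configuration."""
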