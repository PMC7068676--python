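"""Exception hierarchy for the fibermap pipeline."""


class FibermapError(Exception):
    """Base class for all fibermap errors."""


class GeometryError(FibermapError, ValueError):
    """Stack geometry is inconsistent with the image data or itself."""


class FormatError(FibermapError, ValueError):
    """An input file does not conform to the documented layout."""


class DomainError(FibermapError, ValueError):
    """An argument lies outside the operation's mathematical domain."""


class ConfigurationError(FibermapError, ValueError):
    """Mutually inconsistent pipeline/rendering parameters."""


class GenerationError(FibermapError, RuntimeError):
    """Synthetic-field generation could not satisfy its placement spec."""
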