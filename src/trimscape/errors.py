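"""Exception types shared across the pipeline."""


class TrimscapeError(Exception):
    """Base class for all pipeline errors."""


class SizingError(TrimscapeError):
    """A simulated genome or element cannot host what was requested."""


class FormatError(TrimscapeError):
    """Malformed sequence or table input (non-IUPAC characters, bad context...)."""


class FlankError(TrimscapeError):
    """An element lacks the flanking sequence an operation requires."""


class AnnotationError(TrimscapeError):
    """A gene annotation is missing required features."""


class ConfigurationError(TrimscapeError):
    """Inconsistent or incomplete run configuration."""
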