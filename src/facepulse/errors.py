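"""Exception hierarchy shared across the package."""


class FacePulseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FacePulseError):
    """A file does not conform to the expected dialect (missing column, bad header...)."""


class ParseError(FacePulseError):
    """A cell inside an otherwise well-formed file could not be parsed."""


class CoverageError(FacePulseError):
    """A pulse series does not cover the session duration."""


class AnnotationError(FacePulseError):
    """An utterance annotation lies outside the session bounds or is malformed."""


class DegenerateFaceError(FacePulseError):
    """The nasal-bridge normalization length is zero."""


class EmptyDatasetError(FacePulseError):
    """A preprocessing step removed every row."""


class ClassMissingError(FacePulseError):
    """A class-balancing or training step requires both classes present."""


class SchemaError(FacePulseError):
    """Feature columns of a dataset do not match the model's training schema."""


class ConfigError(FacePulseError):
    """A configuration is internally inconsistent or infeasible."""
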