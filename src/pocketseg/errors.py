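"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class PocketsegError(Exception):
    """Base class for package errors."""


class FormatError(PocketsegError):
    """Unparseable or structurally invalid input file."""


class EmptyStructureError(PocketsegError):
    """No protein atoms survive parsing/cleaning."""


class FeaturizationError(PocketsegError):
    """Chemistry perception or grid featurization failed."""


class ConfigError(PocketsegError):
    """Invalid or inconsistent configuration."""


class GeometryError(PocketsegError):
    """Mismatched grid geometry between paired grids."""


class CheckpointError(PocketsegError):
    """Checkpoint missing or incompatible with the model architecture."""
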