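"""Exception hierarchy for the phantom generator.

Every stage raises a subclass of :class:`PhantomError`, so callers (and the
CLI) can map failures to distinct exit codes without string matching.
"""


class PhantomError(Exception):
    """Base class for all generator errors."""


class ConfigError(PhantomError):
    """Invalid configuration, spec, or precondition violation."""


class FormatError(PhantomError):
    """Unreadable or inconsistent volume file / container."""


class PlacementError(PhantomError):
    """A lymph node could not be placed under the non-overlap constraints."""


class StageError(PhantomError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage {stage}] {cause}")
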