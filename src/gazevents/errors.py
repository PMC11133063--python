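"""Exception hierarchy.

All package-raised exceptions derive from :class:`GazeventsError` so callers
can catch everything with one handler while still distinguishing file-format
problems from data-invariant violations and pipeline failures.
"""


class GazeventsError(Exception):
    """Base class for all errors raised by gazevents."""


class FormatError(GazeventsError):
    """A file does not match the expected on-disk schema."""


class DataError(GazeventsError):
    """Input data violates a documented invariant (e.g. bad label, non-monotonic time)."""


class ValidationError(GazeventsError):
    """An argument or configuration value is invalid."""


class PipelineError(GazeventsError):
    """A processing stage failed on otherwise well-formed input."""


class SynchronizationError(PipelineError):
    """Gaze and video time spans do not overlap."""


class ChannelError(PipelineError):
    """A feature channel cannot be interpolated (too few valid knots)."""

    def __init__(self, channel: str, message: str):
        self.channel = channel
        super().__init__(f"channel '{channel}': {message}")


class BalancingError(GazeventsError):
    """A class-balancing quota cannot be met."""


class TrainingError(GazeventsError):
    """The classifier cannot be trained on the given data."""
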