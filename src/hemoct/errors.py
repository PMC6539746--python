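"""Exception hierarchy for hemoct."""


class HemoctError(Exception):
    """Base class for all hemoct errors."""


class FormatError(HemoctError):
    """A file or file series is malformed or internally inconsistent."""


class FitError(HemoctError):
    """A model fit is impossible on the given inputs."""


class MetricsError(HemoctError):
    """A metric is undefined on the given inputs."""


class PlanningError(HemoctError):
    """A cross-validation plan cannot be constructed."""


class UsageError(HemoctError):
    """A pipeline stage was invoked with incompatible options."""
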