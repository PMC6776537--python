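"""Exception hierarchy for htrkit.

All htrkit-specific failures derive from :class:`HtrkitError` so callers
(and the CLI) can distinguish input/usage problems from genuine bugs.
"""


class HtrkitError(Exception):
    """Base class for all htrkit errors."""


class FormatError(HtrkitError):
    """Malformed or inconsistent on-disk input (CSV/WAV/JSON)."""


class ParameterError(HtrkitError):
    """Invalid parameter value (band edges, window lengths, tolerances...)."""


class DegenerateSignalError(HtrkitError):
    """Signal unusable for detection (e.g. zero variance, zero threshold)."""


class ChannelError(HtrkitError):
    """A required recording channel is absent."""


class InsufficientDataError(HtrkitError):
    """Too few data points for the requested fit or statistic."""
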