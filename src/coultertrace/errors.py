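"""Exception hierarchy for coultertrace.

Exit-code mapping used by the CLI: usage errors exit 2 (click default),
FormatError 3, QCAbortError 4.
"""


class CoulterTraceError(Exception):
    """Base class for all coultertrace errors."""


class FormatError(CoulterTraceError):
    """A file does not conform to the fixture dialect (missing header
    field, truncated pulse block, unrecognized magic, ...)."""


class ConsistencyError(CoulterTraceError):
    """Internally inconsistent data (cumulative counts decreasing, time
    section not matching the pulse count, overlapping recordings, ...)."""


class ConfigError(CoulterTraceError):
    """Invalid configuration value (non-positive header constant,
    fraction outside [0, 1), unknown config key, ...)."""


class QCAbortError(CoulterTraceError):
    """QC refused to proceed (e.g. more than half the files flagged as
    debris, suggesting persistent aperture occlusion)."""
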