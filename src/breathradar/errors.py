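"""Exception hierarchy shared across the package."""


class BreathRadarError(ValueError):
    """Base class for all package-specific errors."""


class InvalidScenarioError(BreathRadarError):
    """A scenario specification violates its invariants."""


class UnknownPresetError(BreathRadarError, KeyError):
    """Requested scenario preset does not exist."""


class EmptyTraceError(BreathRadarError):
    """An operation received a trace with no samples."""


class ConfigError(BreathRadarError):
    """A configuration value is inconsistent with the data it is applied to."""


class NoHoldFoundError(BreathRadarError):
    """No breath-hold interval satisfying the quiet criterion was found."""


class InsufficientPeaksError(BreathRadarError):
    """Fewer than two breath peaks were detected; no period can be formed."""


class TraceFormatError(BreathRadarError):
    """A trace file does not conform to the two-column CSV contract."""


class MonotonicTimeError(BreathRadarError):
    """Monitor time stepped backwards."""
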