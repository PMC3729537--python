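"""Exception hierarchy for the emgintent pipeline."""


class EmgIntentError(Exception):
    """Base class for all emgintent errors."""


class ConfigError(EmgIntentError):
    """Invalid configuration value or unknown option."""


class NoMovementError(EmgIntentError):
    """Speed trace has no positive peak; no movement can be detected."""


class TrialTooShortError(EmgIntentError):
    """Not enough samples around the onset to extract the analysis window."""


class DegenerateSignalError(EmgIntentError):
    """A signal is constant (or numerically so) where variation is required."""


class DegenerateSeparationError(EmgIntentError):
    """Two class means coincide; the between-class distance is zero."""


class ChannelMismatchError(EmgIntentError):
    """Channel sets differ where a shared channel layout is required."""
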