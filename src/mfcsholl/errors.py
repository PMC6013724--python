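"""Exception hierarchy for the chamber-analysis pipeline."""


class MfcShollError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MfcShollError):
    """Invalid configuration value or an input inconsistent with the config."""


class DegenerateImageError(MfcShollError):
    """An image carries no usable structure (e.g. constant intensity)."""


class AlignmentFailureError(MfcShollError):
    """Chamber alignment could not be established.

    ``candidates`` carries diagnostic information (e.g. candidate line
    positions) when available.
    """

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates


class NormalizationError(MfcShollError):
    """Profile normalization is impossible (non-positive soma count)."""


class ValidationError(MfcShollError):
    """Invalid domain object or an ill-posed statistical design."""
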