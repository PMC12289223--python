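"""Exception hierarchy shared across the package."""


class AmbuBRSError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AmbuBRSError):
    """A parameter or metadata value is missing or out of its valid range."""


class ValidationError(AmbuBRSError):
    """Input data violates a documented contract (lengths, ordering, signs)."""


class SignalIOError(AmbuBRSError, IOError):
    """A record or annotation file could not be read or written."""


class WindowRejected(AmbuBRSError):
    """An analysis window cannot be estimated; carries a machine-readable reason.

    Reasons used by the package: ``too_short`` (fewer usable samples than one
    spectral segment), ``gap`` (a beat gap longer than the bridgeable maximum),
    ``band_unresolved`` (no frequency bin falls inside the requested band).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)
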