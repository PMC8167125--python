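"""Exception hierarchy shared across the package."""


class FluorTrackError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FluorTrackError):
    """Invalid domain object (polygon, parameters, configuration)."""


class LayoutError(FluorTrackError):
    """Video frame layout incompatible with the requested split."""


class SynchronizationError(FluorTrackError):
    """Paired video sources disagree in frame count."""


class FormatError(FluorTrackError):
    """File content does not match the documented on-disk format."""


class NoInflowError(FluorTrackError):
    """Trace never rises above baseline by the latency threshold."""


class TrackingLostError(FluorTrackError):
    """Too few valid feature points survive to propagate the ROI."""
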