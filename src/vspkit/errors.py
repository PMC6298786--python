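"""Exception hierarchy shared across the analysis stages."""


class VspkitError(Exception):
    """Base class for all vspkit errors."""


class MissingAnnotationError(VspkitError):
    """A required atom role, selection or phosphorus annotation is absent."""


class ConfigurationError(VspkitError):
    """A classifier or protocol configuration is inconsistent or incomplete."""


class DegenerateOrientationError(VspkitError):
    """The orientation vectors are collinear: the cross product vanishes."""


class ProtocolError(VspkitError):
    """A sweep window lies outside the recorded trace or the protocol is malformed."""


class NormalizationError(VspkitError):
    """A normalization reference is zero, missing, or of the wrong sign."""


class FitError(VspkitError):
    """A nonlinear fit failed to converge or was ill-conditioned."""
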