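"""Exception hierarchy for the DECT texture pipeline."""


class DectextureError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DectextureError):
    """Invalid phantom or run configuration."""


class CoregistrationError(DectextureError):
    """Volumes, iodine map and mask do not share one voxel grid."""


class RoiError(DectextureError):
    """ROI mask is empty, too small, or otherwise unusable."""


class InputError(DectextureError):
    """Input data violate a precondition (missing class, missing map, ...)."""
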