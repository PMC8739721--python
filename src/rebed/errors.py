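"""Exception hierarchy."""


class RebedError(Exception):
    """Base class for all package errors."""


class DoseFormatError(RebedError):
    """A dose/image file is malformed or uses unsupported metadata."""


class RasterizationError(RebedError):
    """Structure contours could not be rasterized onto the target grid."""


class RegistrationError(RebedError):
    """Image registration failed or could not be initialised."""


class ConfigError(RebedError):
    """A run configuration is inconsistent or incomplete."""
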