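"""Exception hierarchy shared across the package."""


class PspwedgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PspwedgeError):
    """Invalid, inconsistent, or unparseable run configuration."""


class GeometryError(PspwedgeError):
    """Phantom geometry that cannot be realised on the pixel grid."""


class FormatError(PspwedgeError):
    """Malformed image file (wrong magic number, maxval, or truncation)."""


class UndefinedMetricError(PspwedgeError):
    """A metric whose defining formula divides by zero (noiseless ROI)."""


class InsufficientDataError(PspwedgeError):
    """Fewer than two defined replicate values for a condition."""


class LayoutError(PspwedgeError):
    """Unbalanced or incomplete factorial layout passed to the ANOVA."""
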