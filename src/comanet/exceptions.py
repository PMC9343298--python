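"""Exception types shared across the package."""


class ComanetError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(ComanetError, ValueError):
    """Invalid configuration (degenerate grid, bad batch size, ...)."""


class ShapeError(ComanetError, ValueError):
    """A layer cascade or volume grid produced/required an impossible shape."""


class DegenerateRangeError(ComanetError, ValueError):
    """Intensity normalization fitted on constant data (vmax == vmin)."""


class ValidationError(ComanetError, ValueError):
    """A volume or table failed validation (NaN voxels, wrong dimensionality, ...)."""
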