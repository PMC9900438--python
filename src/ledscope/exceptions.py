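"""Toolkit-specific exception types."""


class ConfigError(ValueError):
    """Invalid or incomplete optics/LED configuration."""


class FormatError(ValueError):
    """Unsupported or corrupt file format."""


class CalibrationError(RuntimeError):
    """A calibration procedure failed its own sanity checks."""


class GridMismatchError(ValueError):
    """Two arrays that must share a pixel grid do not."""


class SigmaOutOfRangeError(ValueError):
    """Requested coherence parameter is unattainable on the configured array.

    Carries ``max_sigma``, the largest coherence parameter the array geometry
    can realize.
    """

    def __init__(self, sigma: float, max_sigma: float):
        self.sigma = sigma
        self.max_sigma = max_sigma
        super().__init__(
            f"coherence parameter {sigma:.3g} is unattainable on this LED array; "
            f"maximum attainable sigma is {max_sigma:.3g}"
        )
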