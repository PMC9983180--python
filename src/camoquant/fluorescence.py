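"""Red-fluorescent body area from fluorescence photographs.

Fluorescence photos are taken under cyan excitation with a red camera
filter, so only fluorescent emission reaches the sensor; the red channel on
a 0-255 scale carries the signal.  Photos of one individual may differ in
shutter speed and are first equalized to a common exposure; the fluorescent
area is then the number of body-mask pixels at or above a fixed brightness
threshold (default 100), reported as an absolute pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FluorescenceImage", "equalize_exposure", "fluorescent_area",
           "FLUORESCENCE_THRESHOLD"]

#: Brightness below this (0-255 scale) is treated as noise; pixels exactly
#: at the threshold are retained.
FLUORESCENCE_THRESHOLD = 100.0


@dataclass
class FluorescenceImage:
    """Red channel of one fluorescence photo plus body mask and shutter time."""

    red_channel: np.ndarray
    body_mask: np.ndarray
    shutter_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.red_channel = np.asarray(self.red_channel, dtype=float)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.red_channel.ndim != 2:
            raise ValueError("red_channel must be 2-D")
        if self.body_mask.shape != self.red_channel.shape:
            raise ValueError("body_mask shape must match red_channel")
        if self.red_channel.min() < 0 or self.red_channel.max() > 255:
            raise ValueError("red_channel values must lie in [0, 255]")
        if self.shutter_s <= 0:
            raise ValueError("shutter time must be positive")

    @classmethod
    def from_16bit(cls, red_channel: np.ndarray, body_mask: np.ndarray,
                   shutter_s: float, **kw) -> "FluorescenceImage":
        """Accept a 16-bit red channel, rescaled to the 0-255 working scale."""
        red = np.asarray(red_channel, dtype=float) * (255.0 / 65535.0)
        return cls(red, body_mask, shutter_s, **kw)


def equalize_exposure(images: list[FluorescenceImage],
                      reference_shutter_s: float) -> list[FluorescenceImage]:
    """Scale each image to a common shutter speed (linear exposure model).

    Values are multiplied by reference_shutter / shutter and clipped at 255.
    """
    if reference_shutter_s <= 0:
        raise ValueError("reference shutter must be positive")
    out = []
    for img in images:
        factor = reference_shutter_s / img.shutter_s
        scaled = np.clip(img.red_channel * factor, 0.0, 255.0)
        new = replace(img, red_channel=scaled, shutter_s=reference_shutter_s)
        new.meta = dict(img.meta, exposure_factor=factor)
        out.append(new)
    return out


def fluorescent_area(img: FluorescenceImage,
                     threshold: float = FLUORESCENCE_THRESHOLD,
                     scale_px_per_cm: float | None = None) -> float:
    """Count body-mask pixels with red value >= threshold.

    Pixels exactly at the threshold count as fluorescent (only values
    *below* it are removed as noise).  Returns an absolute pixel count, or
    an area in cm^2 when a pixel scale is supplied.
    """
    if not img.body_mask.any():
        raise ValueError("empty body mask")
    count = int(np.count_nonzero(img.red_channel[img.body_mask] >= threshold))
    if scale_px_per_cm is not None:
        return count / scale_px_per_cm**2
    return count
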