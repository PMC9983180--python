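"""Calibrated trial-image pipeline.

A trial photograph contains the fish, a patch of the background it sits on,
and two embedded diffuse grey standards of known reflectance (12% and 72%).
The pipeline (1) normalizes camera-linear pixel values to reflectance with a
per-channel affine map anchored at the two standards, (2) converts
reflectance to per-pixel cone catches through a linear camera-to-cone
mapping, (3) optionally applies an acuity-matched Gaussian blur and an
RNL-gated smoothing filter, and (4) measures mean cone catches for regions
of interest, from which luminance, hue and JND contrasts are derived.

Pixel coordinates are row-major and 0-based; bounding boxes are half-open
``(row0, row1, col0, col1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .observers import Observer
from .rnl import (
    ConeCatchVector,
    achromatic_jnd,
    chromatic_jnd,
    chromatic_jnd_arrays,
    hue_index,
    luminance_index,
)

__all__ = [
    "TrialImage",
    "StandardPatch",
    "ROI",
    "normalize_with_standards",
    "to_cone_catch_image",
    "acuity_blur",
    "rnl_ranked_filter",
    "measure_roi",
    "trial_metrics",
    "average_timepoints",
    "CATCH_FLOOR",
]

#: Small positive floor applied to cone-catch pixels before log-domain use.
CATCH_FLOOR = 1e-6


@dataclass(frozen=True)
class StandardPatch:
    """An embedded diffuse grey standard: half-open bbox + nominal reflectance."""

    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    nominal_reflectance: float

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.bbox
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"empty standard bbox {self.bbox}")
        if not 0.0 < self.nominal_reflectance < 1.0:
            raise ValueError("nominal reflectance must be in (0, 1)")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        m[r0:r1, c0:c1] = True
        return m


@dataclass(frozen=True)
class ROI:
    """A measurement region: boolean mask plus a label (body / background / patch)."""

    mask: np.ndarray
    label: str = "body"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ROI mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "mask", m)


@dataclass
class TrialImage:
    """H x W x C linear image with calibration standards and a pixel scale.

    channel_meaning tracks where the image sits in the pipeline:
    ``camera-linear`` (raw linear counts), ``reflectance`` (after standard
    normalization) or ``cone-catch`` (after observer mapping).
    """

    pixels: np.ndarray
    channel_meaning: str = "camera-linear"
    scale_px_per_cm: float = 10.0
    standards: tuple[StandardPatch, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (2, 3):
            raise ValueError("pixels must be H x W x C with C in {2, 3}")
        if self.scale_px_per_cm <= 0:
            raise ValueError("scale_px_per_cm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def normalize_with_standards(img: TrialImage) -> TrialImage:
    """Map camera-linear pixels to reflectance via the two grey standards.

    Fits, per channel, the affine map through the two points
    (mean pixel value over a standard, its nominal reflectance).  Two
    standards determine slope and intercept exactly, so each standard's mean
    maps to its nominal.
    """
    if len(img.standards) != 2:
        raise ValueError("normalization needs exactly two grey standards")
    s1, s2 = img.standards
    shape2d = img.pixels.shape[:2]
    m1 = img.pixels[s1.mask(shape2d)].mean(axis=0)  # per-channel means
    m2 = img.pixels[s2.mask(shape2d)].mean(axis=0)
    if np.any(np.abs(m2 - m1) < 1e-12):
        raise ValueError("degenerate standards: equal channel means, affine map undefined")
    slope = (s2.nominal_reflectance - s1.nominal_reflectance) / (m2 - m1)
    intercept = s1.nominal_reflectance - slope * m1
    out = img.pixels * slope + intercept
    return replace(img, pixels=out, channel_meaning="reflectance")


def to_cone_catch_image(img: TrialImage, obs: Observer,
                        mapping: np.ndarray | None = None) -> TrialImage:
    """Per-pixel linear map from reflectance channels to cone catches.

    ``mapping`` is a (n_cones x C) matrix combining camera spectral
    sensitivity and the observer's cones; it is camera-specific and supplied
    by the user.  ``None`` means the identity (channels already are catches,
    the synthetic pathway).  Output pixels are floored at ``CATCH_FLOOR``
    so downstream log-domain operations are defined.
    """
    C = img.pixels.shape[2]
    if mapping is None:
        mapping = np.eye(C)
    mapping = np.asarray(mapping, dtype=float)
    if mapping.shape != (obs.n_cones, C):
        raise ValueError(
            f"mapping shape {mapping.shape} incompatible with {C} channels "
            f"and {obs.n_cones} cones"
        )
    out = np.einsum("ij,hwj->hwi", mapping, img.pixels)
    out = np.maximum(out, CATCH_FLOOR)
    new = replace(img, pixels=out, channel_meaning="cone-catch")
    new.meta = dict(img.meta, observer=obs.name, observer_obj=obs)
    return new


def acuity_sigma_px(obs: Observer, scale_px_per_cm: float) -> float:
    """Gaussian sigma in pixels matching the observer's minimum resolvable angle.

    The blur FWHM equals the minimum resolvable angle (1/acuity degrees)
    projected at the viewing distance:
    px_per_degree = scale * distance * tan(1 deg);
    sigma = (px_per_degree / acuity) / (2 sqrt(2 ln 2)).
    """
    if obs.acuity_cpd is None or obs.viewing_distance_cm is None:
        raise ValueError(f"observer {obs.name!r} has no acuity/viewing distance")
    px_per_degree = scale_px_per_cm * obs.viewing_distance_cm * np.tan(np.deg2rad(1.0))
    fwhm = px_per_degree / obs.acuity_cpd
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def acuity_blur(img: TrialImage, obs: Observer) -> TrialImage:
    """Blur the image to the observer's spatial acuity (symmetric boundary).

    If the implied sigma is below 0.3 px the observer out-resolves the
    sampling and the image is returned unchanged with a warning.
    """
    sigma = acuity_sigma_px(obs, img.scale_px_per_cm)
    if sigma < 0.3:
        warnings.warn(
            f"acuity sigma {sigma:.3f} px below 0.3 px; blur skipped", stacklevel=2
        )
        return img
    out = np.empty_like(img.pixels)
    for c in range(img.pixels.shape[2]):
        out[:, :, c] = ndimage.gaussian_filter(img.pixels[:, :, c], sigma, mode="reflect")
    return replace(img, pixels=out)


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def rnl_ranked_filter(img: TrialImage, obs: Observer, radius: int = 2,
                      n_iter: int = 1) -> TrialImage:
    """JND-gated smoothing: pool each pixel with perceptually equal neighbours.

    Each pixel is replaced by the mean of the neighbours within ``radius``
    (itself included) whose chromatic JND to the pixel is below 1 — a
    simplified analogue of RNL ranked filtering that removes sub-threshold
    noise while leaving supra-threshold edges in place.  Uniform regions are
    fixed points, and piecewise-constant images whose regions differ by
    more than 1 JND pass through unchanged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if img.channel_meaning != "cone-catch":
        raise ValueError("RNL filtering operates on cone-catch images")
    pixels = np.maximum(img.pixels, CATCH_FLOOR)
    offsets = _disk_offsets(radius)
    for _ in range(n_iter):
        # mirror padding keeps the pooling operator symmetric, so the global
        # mean is preserved exactly whenever the JND gate passes everything
        padded = np.pad(
            pixels, ((radius, radius), (radius, radius), (0, 0)), mode="symmetric"
        )
        acc = np.zeros_like(pixels)
        cnt = np.zeros(pixels.shape[:2])
        H, W = pixels.shape[:2]
        for dy, dx in offsets:
            nb = padded[radius + dy : radius + dy + H, radius + dx : radius + dx + W, :]
            jnd = chromatic_jnd_arrays(pixels, nb, obs)
            ok = jnd < 1.0
            acc += nb * ok[:, :, None]
            cnt += ok
        pixels = acc / cnt[:, :, None]
    out = replace(img, pixels=pixels)
    out.meta = dict(img.meta, rnl_filter="simplified-jnd-gated-mean")
    return out


def measure_roi(img: TrialImage, roi: ROI) -> ConeCatchVector:
    """Per-cone mean catch over an ROI mask."""
    if img.channel_meaning != "cone-catch":
        raise ValueError("measure_roi expects a cone-catch image")
    observer = img.meta.get("observer_obj")
    if observer is None:
        raise ValueError("image lacks observer metadata; convert with to_cone_catch_image "
                         "and attach meta['observer_obj']")
    if roi.mask.shape != img.pixels.shape[:2]:
        raise ValueError("ROI mask shape does not match image")
    q = img.pixels[roi.mask].mean(axis=0)
    return ConeCatchVector(observer, tuple(q))


def trial_metrics(body: ConeCatchVector, background: ConeCatchVector) -> dict:
    """Per-trial responses: body luminance and hue, body-vs-background JNDs."""
    out = {
        "luminance": luminance_index(body),
        "achromatic_jnd": achromatic_jnd(body, background),
        "chromatic_jnd": chromatic_jnd(body, background),
    }
    out["hue"] = hue_index(body) if body.observer.n_cones == 3 else np.nan
    return out


_ID_KEYS = ("fish_id", "species", "background", "observer")


def average_timepoints(rec1: dict, rec2: dict) -> dict:
    """Average the two adaptation time points (minute 1 and minute 5).

    The records must describe the same fish x background x observer cell;
    numeric response fields are averaged, identifiers carried through.
    """
    for k in _ID_KEYS:
        if k in rec1 or k in rec2:
            if rec1.get(k) != rec2.get(k):
                raise ValueError(f"cannot average records differing in {k!r}")
    out = {k: rec1[k] for k in _ID_KEYS if k in rec1}
    for k, v in rec1.items():
        if k in _ID_KEYS or k in ("time_min",):
            continue
        if k not in rec2:
            raise ValueError(f"field {k!r} missing from second record")
        out[k] = 0.5 * (float(v) + float(rec2[k]))
    return out
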