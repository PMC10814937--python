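"""Color-space representations and conversions for lesion color analysis.

Clinical photographs are 8-bit sRGB. Analysis additionally uses the CIELAB
space (D65 white point, 2° standard observer), whose lightness L* and
opponent axes a* (green–red) and b* (blue–yellow) are approximately
perceptually uniform, and the Individual Typology Angle

    ITA = arctan((L* − 50) / b*) · 180/π   [degrees]

a spectrophotometric index of skin pigmentation: higher ITA means lighter
skin. Here ITA is used as a lesion-vs-normal-skin color-change index rather
than for phototype classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGBTriple",
    "LabTriple",
    "ColorSummary",
    "ChannelHistogram",
    "CHANNEL_NAMES",
    "rgb_to_lab",
    "lab_to_rgb",
    "ita_from_lab",
    "region_histograms",
    "image_to_lab",
]

CHANNEL_NAMES = ("red", "green", "blue")


@dataclass(frozen=True)
class RGBTriple:
    """Mean channel intensities of a region, each in [0, 255]."""

    red: float
    green: float
    blue: float

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} component {v!r} outside [0, 255]")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.red, self.green, self.blue], dtype=float)


@dataclass(frozen=True)
class LabTriple:
    """CIELAB coordinates: L* in [0, 100]; a*, b* finite opponent values."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        for name in ("L_star", "a_star", "b_star"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not math.isfinite(self.L_star) or not (0.0 <= self.L_star <= 100.0):
            raise ValueError(f"L* {self.L_star!r} outside [0, 100]")
        if not (math.isfinite(self.a_star) and math.isfinite(self.b_star)):
            raise ValueError("a*/b* must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star], dtype=float)


@dataclass(frozen=True)
class ColorSummary:
    """The seven mean color parameters of one region.

    ``ita`` must be consistent with ``ita_from_lab(lab.L_star, lab.b_star)``
    within reporting tolerance (0.15°, allowing for 2-decimal rounding of
    the L*/b* inputs in transcribed tables).
    """

    rgb: RGBTriple
    lab: LabTriple
    ita: float

    _ITA_TOL = 0.15

    def __post_init__(self) -> None:
        expected = ita_from_lab(self.lab.L_star, self.lab.b_star)
        if abs(expected - self.ita) > self._ITA_TOL:
            raise ValueError(
                f"ITA {self.ita:.3f} inconsistent with L*={self.lab.L_star}, "
                f"b*={self.lab.b_star} (expected {expected:.3f})"
            )

    def as_array(self) -> np.ndarray:
        """Parameters in canonical order: red, green, blue, L*, a*, b*, ITA."""
        return np.concatenate([self.rgb.as_array(), self.lab.as_array(), [self.ita]])


@dataclass(frozen=True)
class ChannelHistogram:
    """256-bin intensity histogram of one RGB channel over a region."""

    channel: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.channel!r}")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,) or (counts < 0).any():
            raise ValueError("counts must be 256 nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        """Write the histogram as two-column CSV (bin, count)."""
        import pandas as pd

        pd.DataFrame({"bin": np.arange(256), "count": self.counts}).to_csv(
            path, index=False
        )


def _validate_rgb01(arr: np.ndarray) -> None:
    if not np.isfinite(arr).all() or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB components must be finite and within [0, 255]")


def rgb_to_lab(rgb: RGBTriple | Iterable[float]) -> LabTriple:
    """Convert one sRGB color (0–255 per channel) to CIELAB.

    Uses the IEC 61966-2-1 sRGB transfer function and the D65 white point
    with the 2° standard observer.
    """
    if not isinstance(rgb, RGBTriple):
        rgb = RGBTriple(*rgb)
    arr = rgb.as_array()[None, None, :] / 255.0
    _validate_rgb01(arr)
    L, a, b = _skcolor.rgb2lab(arr)[0, 0]
    # guard against tiny excursions from float roundoff at the gamut edge
    return LabTriple(min(max(float(L), 0.0), 100.0), float(a), float(b))


def lab_to_rgb(lab: LabTriple | Iterable[float]) -> RGBTriple:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut colors are clipped."""
    if not isinstance(lab, LabTriple):
        lab = LabTriple(*lab)
    arr = lab.as_array()[None, None, :]
    r, g, b = _skcolor.lab2rgb(arr)[0, 0] * 255.0
    return RGBTriple(float(r), float(g), float(b))


def image_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster (H, W, 3) to a float CIELAB raster."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return _skcolor.rgb2lab(image.astype(float) / 255.0)


def ita_from_lab(L_star: float, b_star: float) -> float:
    """Individual Typology Angle in degrees from CIELAB L* and b*.

    ITA = arctan((L* − 50)/b*) · 180/π, in (−90, 90). The formula is
    undefined at b* = 0; by convention this returns +90 for L* > 50,
    −90 for L* < 50 and 0 for L* = 50.
    """
    if not (0.0 <= L_star <= 100.0):
        raise ValueError(f"L* {L_star!r} outside [0, 100]")
    if not math.isfinite(b_star):
        raise ValueError("b* must be finite")
    if b_star == 0.0:
        if L_star > 50.0:
            return 90.0
        if L_star < 50.0:
            return -90.0
        return 0.0
    return math.degrees(math.atan((L_star - 50.0) / b_star))


def region_histograms(
    image: np.ndarray, mask: np.ndarray
) -> tuple[ChannelHistogram, ChannelHistogram, ChannelHistogram]:
    """Per-channel 256-bin histograms over the masked pixels of an image.

    The sum of counts in each histogram equals the mask pixel count.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask dimensions must match the image raster")
    if not mask.any():
        raise ValueError("empty region mask")
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise ValueError("image intensities outside [0, 255]")
        image = np.round(image).astype(np.uint8)
    pixels = image[mask]
    return tuple(
        ChannelHistogram(name, np.bincount(pixels[:, i], minlength=256))
        for i, name in enumerate(CHANNEL_NAMES)
    )
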