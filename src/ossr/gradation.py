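"""Gradation processing: stored DICOM values -> CT numbers -> windowed 16-bit display.

Every downstream stage (registration, training, metrics) consumes images on a
common integer "display" scale spanning ``[0, 255**2]``.  The conversion chain is

1. ``raw_to_ct``     — apply the DICOM rescale (slope/intercept) to obtain CT
   numbers on the Hounsfield-style scale (air −1000, water 0).
2. ``ct_to_display`` — window the CT numbers: map ``[center − width/2,
   center + width/2]`` affinely onto ``[0, 65025]`` and clip.
3. ``normalize``     — divide by 65025 for network consumption; ``denormalize``
   inverts exactly on integer display images.

Rounding in ``ct_to_display``/``denormalize`` is half-away-from-zero, applied
after scaling, so the mapping is deterministic and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Top of the display scale, 255**2 (a "16-bit image from 0 to 255 squared").
DISPLAY_MAX = 255 ** 2


class GradationError(ValueError):
    """Invalid input to a gradation operation."""


@dataclass(frozen=True)
class WindowSettings:
    """CT display window: ``center`` and ``width`` in Hounsfield units.

    The window minimum ``center - width/2`` is always derived, never stored.
    """

    center: float
    width: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.center) and math.isfinite(self.width)):
            raise GradationError("window center/width must be finite")
        if self.width <= 0:
            raise GradationError(f"window width must be > 0, got {self.width}")

    @property
    def minimum(self) -> float:
        return window_minimum(self)


#: Fallback window for raster inputs without DICOM metadata; covers the
#: [-840, 600] HU pelvic soft-tissue display range.
DEFAULT_WINDOW = WindowSettings(center=-120.0, width=1440.0)


@dataclass
class RawScanSlice:
    """One DICOM-derived slice: stored integer pixels plus rescale/window/geometry.

    ``pixels`` holds the stored values ``D``; CT numbers are
    ``rescale_slope * D + rescale_intercept``.
    """

    pixels: np.ndarray
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    window_center: float = DEFAULT_WINDOW.center
    window_width: float = DEFAULT_WINDOW.width
    slice_position: float = 0.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    modality_label: str = "CBCT"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise GradationError("pixels must be a 2-D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            if not np.all(np.isfinite(self.pixels)) or np.any(
                self.pixels != np.round(self.pixels)
            ):
                raise GradationError("pixels must be finite and integral")
        for name in ("rescale_slope", "rescale_intercept", "window_center",
                     "window_width", "slice_position"):
            if not math.isfinite(float(getattr(self, name))):
                raise GradationError(f"{name} must be finite")
        if self.window_width <= 0:
            raise GradationError("window_width must be > 0")
        if any(s <= 0 for s in self.pixel_spacing):
            raise GradationError("pixel_spacing components must be > 0")

    @property
    def window(self) -> WindowSettings:
        return WindowSettings(self.window_center, self.window_width)


def raw_to_ct(raw: RawScanSlice) -> np.ndarray:
    """Convert stored values to CT numbers: ``C = slope * D + intercept``.

    Returns a float64 array of the same shape.
    """
    return raw.rescale_slope * raw.pixels.astype(np.float64) + raw.rescale_intercept


def window_minimum(window: WindowSettings) -> float:
    """Lower edge of the display window, ``center - width/2``."""
    return window.center - window.width / 2.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; imaging convention is half away from zero.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def ct_to_display(ct: np.ndarray, window: WindowSettings) -> np.ndarray:
    """Window CT numbers onto the integer display scale ``[0, 65025]``.

    ``P = round(65025 * (C - m) / width)`` clipped to the display range, with
    ``m`` the window minimum.  Monotone non-decreasing in the CT number.
    """
    ct = np.asarray(ct, dtype=np.float64)
    if not np.all(np.isfinite(ct)):
        raise GradationError("CT image must be finite")
    m = window_minimum(window)
    p = DISPLAY_MAX * (ct - m) / window.width
    p = np.clip(_round_half_away(p), 0, DISPLAY_MAX)
    return p.astype(np.int32)


def raw_to_display(raw: RawScanSlice, window: WindowSettings | None = None) -> np.ndarray:
    """Full gradation chain for one slice; window defaults to the slice's own."""
    return ct_to_display(raw_to_ct(raw), window or raw.window)


def normalize(img: np.ndarray) -> np.ndarray:
    """Map a display image to floats in ``[0, 1]`` (divide by 65025)."""
    img = np.asarray(img)
    if img.min() < 0 or img.max() > DISPLAY_MAX:
        raise GradationError("display image values must lie in [0, 65025]")
    return img.astype(np.float64) / DISPLAY_MAX


def denormalize(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`: scale by 65025, round, clip to the display range.

    Exact round-trip on every integer display image.
    """
    p = np.asarray(arr, dtype=np.float64) * DISPLAY_MAX
    p = np.clip(_round_half_away(p), 0, DISPLAY_MAX)
    return p.astype(np.int32)


def first_scalar(value) -> float:
    """First entry of a possibly multi-valued DICOM tag (deterministic tie-break)."""
    try:
        return float(value[0])
    except (TypeError, IndexError):
        return float(value)
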