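"""Per-frame image-quality metrics and the binary quality gate.

Two scores drive the gate used by the sequence pooling mechanism:

* **brightness** — mean pixel intensity on the 0-255 scale.  Very dark
  frames indicate acoustic shadowing; very bright ones indicate gain
  artifacts.  The operating band is 10-30.
* **blurriness** — the variance of the discrete Laplacian of the
  Gaussian-smoothed frame (variance-of-Laplacian focus measure).  A low
  value means a blurry frame.  The operating band is [200, 300): frames
  scoring below 200 or at/above 300 are excluded.

A frame's gate weight ``w`` is 1 only when both scores fall inside their
bands; gated-out frames do not contribute to the pooled malignancy score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frame_io import Frame

#: 4-neighbour discrete Laplacian (sum of second partial derivatives).
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class QualityThresholds:
    """Gate bands: brightness in [min, max] (closed), blurriness in [min, max)."""

    brightness_min: float = 10.0
    brightness_max: float = 30.0
    blur_min: float = 200.0
    blur_max: float = 300.0

    def __post_init__(self) -> None:
        if not self.brightness_min < self.brightness_max:
            raise ValueError("brightness_min must be < brightness_max")
        if not self.blur_min < self.blur_max:
            raise ValueError("blur_min must be < blur_max")


@dataclass(frozen=True)
class FrameQuality:
    brightness: float
    blurriness: float
    gate: int


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel truncated at radius ceil(3*sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(3.0 * sigma))
    coords = np.arange(-radius, radius + 1, dtype=float)
    p, q = np.meshgrid(coords, coords, indexing="ij")
    kernel = np.exp(-(p**2 + q**2) / (2.0 * sigma**2))
    return kernel / kernel.sum()


def _pixels(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.pixels
    return np.asarray(frame, dtype=float)


def gaussian_smooth(frame, sigma: float) -> np.ndarray:
    """Convolve with the normalized Gaussian kernel, reflective boundaries.

    Returns a real-valued array (no re-quantization) of the same size.
    """
    kernel = gaussian_kernel(sigma)
    return ndimage.convolve(_pixels(frame), kernel, mode="reflect")


def laplacian(image: np.ndarray) -> np.ndarray:
    """4-neighbour discrete Laplacian with reflective boundary handling."""
    return ndimage.convolve(np.asarray(image, dtype=float), LAPLACIAN_KERNEL, mode="reflect")


def blurriness_score(frame, sigma: float = 1.0) -> float:
    """Variance of the Laplacian of the Gaussian-smoothed frame.

    Population variance (divide by pixel count).  Low = blurry, high = sharp.
    """
    smoothed = gaussian_smooth(frame, sigma)
    lap = laplacian(smoothed)
    return float(np.var(lap))


def brightness_score(frame) -> float:
    """Mean pixel intensity on the 0-255 scale."""
    return float(np.mean(_pixels(frame)))


def gate_from_scores(brightness: float, blurriness: float, thresholds: QualityThresholds) -> int:
    """Binary gate: 1 iff brightness in [b_min, b_max] and blurriness in [l_min, l_max)."""
    bright_ok = thresholds.brightness_min <= brightness <= thresholds.brightness_max
    blur_ok = thresholds.blur_min <= blurriness < thresholds.blur_max
    return int(bright_ok and blur_ok)


def assess_frame(
    frame,
    thresholds: QualityThresholds = QualityThresholds(),
    sigma: float = 1.0,
    on_resized: bool = False,
) -> FrameQuality:
    """Compute both quality scores and the gate for one frame.

    By default the scores are evaluated on the frame's native-resolution
    pixels (resizing rescales the Laplacian-variance measure, so the default
    thresholds are tied to native frames); pass ``on_resized=True`` to score
    the working-geometry pixels instead.
    """
    if isinstance(frame, Frame):
        pixels = frame.quality_pixels(on_resized=on_resized)
    else:
        pixels = np.asarray(frame, dtype=float)
    brightness = brightness_score(pixels)
    blurriness = blurriness_score(pixels, sigma=sigma)
    return FrameQuality(
        brightness=brightness,
        blurriness=blurriness,
        gate=gate_from_scores(brightness, blurriness, thresholds),
    )
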