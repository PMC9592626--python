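"""Sonochemiluminescence (SCL) photograph quantification.

Luminol solutions emit faint blue light (~430 nm) where cavitation-generated
hydroxyl radicals oxidize the luminol, so a long-exposure photograph of a
sonicated well carries a spatial map of cavitation activity.  The standard
quantification is: subtract a dark background frame pixel-by-pixel, select a
circular region of interest (ROI) covering the glowing well, and average the
blue channel over the pixels inside it.  The resulting spatial average,
``I_SCL`` in raw 8-bit counts, is a relative (not absolute) measure of
hydroxyl-radical production.

Conventions
-----------
* Background subtraction clamps negative differences to zero, mirroring
  8-bit image-calculator behaviour.
* ROI membership is a pixel-center test:
  ``(x - cx)**2 + (y - cy)**2 <= radius**2`` with x the column index and
  y the row index.
* Only the blue channel is quantified; red and green are kept for
  diagnostics.  No radiometric calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SCLImage",
    "CircularROI",
    "SCLResult",
    "subtract_background",
    "mean_blue",
    "detect_roi",
    "batch_quantify",
    "NoSignalError",
]


class NoSignalError(RuntimeError):
    """No pixel exceeds the detection threshold: no detectable SCL emission."""


@dataclass(frozen=True)
class SCLImage:
    """An 8-bit RGB well photograph with acquisition metadata.

    ``pixels`` has shape (height, width, 3), dtype uint8.  Metadata fields
    record the acquisition conditions and are carried through processing.
    """

    pixels: np.ndarray
    exposure_s: float | None = None
    power_density_w_cm2: float | None = None
    sonication_time_s: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[:, :, 2]

    @classmethod
    def open(cls, path: str, **metadata) -> "SCLImage":
        """Read a PNG/TIFF photograph, converting to 8-bit RGB if needed."""
        with Image.open(path) as im:
            return cls(np.asarray(im.convert("RGB")), **metadata)

    def save(self, path: str) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest in pixel coordinates (x = column, y = row)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def validate_inside(self, image: SCLImage) -> None:
        if (
            self.center_x - self.radius < -0.5
            or self.center_y - self.radius < -0.5
            or self.center_x + self.radius > image.width - 0.5
            or self.center_y + self.radius > image.height - 0.5
        ):
            raise ValueError("ROI circle extends outside the image")

    def mask(self, image: SCLImage) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the circle."""
        yy, xx = np.mgrid[0 : image.height, 0 : image.width]
        return (xx - self.center_x) ** 2 + (yy - self.center_y) ** 2 <= self.radius**2


@dataclass(frozen=True)
class SCLResult:
    """Spatial-average blue intensity over one ROI, with its provenance."""

    mean_blue: float
    n_pixels: int
    roi: CircularROI
    power_density_w_cm2: float | None = None
    sonication_time_s: float | None = None
    exposure_s: float | None = None


def subtract_background(image: SCLImage, background: SCLImage) -> SCLImage:
    """Pixel-by-pixel background subtraction, clamped below at zero."""
    if image.pixels.shape != background.pixels.shape:
        raise ValueError("image and background dimensions differ")
    diff = image.pixels.astype(np.int16) - background.pixels.astype(np.int16)
    return replace(image, pixels=np.clip(diff, 0, 255).astype(np.uint8))


def mean_blue(image: SCLImage, roi: CircularROI) -> SCLResult:
    """Arithmetic mean of the blue channel over the ROI pixels."""
    roi.validate_inside(image)
    mask = roi.mask(image)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI contains no pixel centers")
    return SCLResult(
        mean_blue=float(image.blue[mask].mean()),
        n_pixels=n,
        roi=roi,
        power_density_w_cm2=image.power_density_w_cm2,
        sonication_time_s=image.sonication_time_s,
        exposure_s=image.exposure_s,
    )


def detect_roi(image: SCLImage, threshold: float = 10.0) -> CircularROI:
    """Detect the glowing well as a circle from bright blue pixels.

    Pixels with blue value strictly above ``threshold`` (on the
    background-subtracted image) define the emitting region; the ROI is
    centered on their centroid with radius ``sqrt(2)`` times their RMS
    distance from it — exact for a uniformly lit disk.  A manually supplied
    :class:`CircularROI` always takes precedence over detection.
    """
    ys, xs = np.nonzero(image.blue > threshold)
    if xs.size == 0:
        raise NoSignalError("no pixel above threshold: no detectable SCL emission")
    cx, cy = float(xs.mean()), float(ys.mean())
    rms = float(np.sqrt(((xs - cx) ** 2 + (ys - cy) ** 2).mean()))
    radius = max(np.sqrt(2.0) * rms, 0.5)
    # keep the circle inside the frame
    radius = min(
        radius,
        cx + 0.5,
        cy + 0.5,
        image.width - 0.5 - cx,
        image.height - 0.5 - cy,
    )
    if radius <= 0:
        raise NoSignalError("detected emission region collapses to the image border")
    return CircularROI(center_x=cx, center_y=cy, radius=radius)


def batch_quantify(
    images: list[SCLImage],
    background: SCLImage | None = None,
    roi: CircularROI | None = None,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Quantify a set of images sharing one background and ROI policy.

    Each image must carry distinct (power density, sonication time) metadata;
    the result is a table keyed by those conditions, one row per image,
    matching the bar-chart layout conventional for SCL dose-response panels.
    With ``roi=None`` the ROI is auto-detected per image after subtraction.
    """
    rows = []
    seen = set()
    for img in images:
        key = (img.power_density_w_cm2, img.sonication_time_s)
        if key in seen:
            raise ValueError(f"duplicate condition key {key}")
        seen.add(key)
        work = subtract_background(img, background) if background is not None else img
        use_roi = roi if roi is not None else detect_roi(work, threshold)
        res = mean_blue(work, use_roi)
        rows.append(
            {
                "power_density_w_cm2": res.power_density_w_cm2,
                "sonication_time_s": res.sonication_time_s,
                "exposure_s": res.exposure_s,
                "I_SCL": res.mean_blue,
                "n_pixels": res.n_pixels,
            }
        )
    columns = ["power_density_w_cm2", "sonication_time_s", "exposure_s", "I_SCL", "n_pixels"]
    return pd.DataFrame(rows, columns=columns)
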