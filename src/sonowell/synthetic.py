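"""Synthetic inputs: canonical study parameters, analytic reference fields,
and simulated SCL photograph pairs with known ground truth.

The image generator emulates what a long-exposure dark-room photograph of a
luminol-emitting well looks like: a nearly black background frame with a
per-channel offset and additive sensor noise, and a signal frame adding a
circular blue glow with a smooth radial profile.  It deliberately does not
model luminol reaction kinetics or any mapping from acoustic intensity to
photon yield — emission amplitude is a free parameter, so the generator
provides ground truth for testing the quantifier, not predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import MediumProperties, SourceDrive, WellGeometry, complex_acoustics
from .scl import SCLImage
from .solver import Column1D, analytic_1d_column

__all__ = ["SCLSceneParams", "FixtureSet", "make_scl_pair", "fixtures", "reference_fields"]

#: the three transducer power densities of the study conditions [W/cm^2]
DRIVE_POWERS_W_CM2 = (0.30, 0.45, 0.60)
#: sonication-time grid of the study conditions [s]
SONICATION_TIMES_S = (5.0, 10.0, 15.0, 30.0, 60.0, 120.0)
#: printed reference values of the bottom-wall displacement [nm]
REFERENCE_DISPLACEMENT_NM = (9.95, 12.19, 14.06)


@dataclass(frozen=True)
class SCLSceneParams:
    """Parameters of one synthetic SCL photograph pair.

    The blue emission profile inside the well disk is
    ``amplitude * (1 - (s/radius)**2) ** profile_shape`` at distance ``s``
    from the center; ``profile_shape = 0`` gives a flat disk.  Noise is
    additive Gaussian on the 8-bit counts, truncated to [0, 255].
    """

    width: int = 160
    height: int = 120
    center_x: float = 80.0
    center_y: float = 60.0
    well_radius: float = 40.0
    amplitude: float = 120.0
    profile_shape: float = 0.5
    background_rgb: tuple[float, float, float] = (3.0, 3.0, 6.0)
    noise_scale: float = 2.0
    seed: int = 0
    allow_saturation: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_scale < 0:
            raise ValueError("amplitude and noise_scale must be non-negative")
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if not self.allow_saturation and self.amplitude + self.background_rgb[2] > 255:
            raise ValueError(
                "amplitude plus blue background exceeds the 8-bit range; "
                "pass allow_saturation=True to generate a clipped image"
            )


def _emission_profile(params: SCLSceneParams) -> np.ndarray:
    """Noiseless blue emission at every pixel center (float counts)."""
    yy, xx = np.mgrid[0 : params.height, 0 : params.width].astype(float)
    s2 = ((xx - params.center_x) ** 2 + (yy - params.center_y) ** 2) / params.well_radius**2
    inside = s2 <= 1.0
    prof = np.zeros_like(s2)
    prof[inside] = params.amplitude * (1.0 - s2[inside]) ** params.profile_shape
    return prof


def _quantize(values: np.ndarray, rng: np.random.Generator, noise: float) -> np.ndarray:
    if noise > 0:
        values = values + rng.normal(0.0, noise, size=values.shape)
    return np.clip(np.rint(values), 0, 255).astype(np.uint8)


def make_scl_pair(params: SCLSceneParams) -> tuple[SCLImage, SCLImage, float]:
    """Generate (background frame, signal frame, ground-truth ROI mean).

    Both frames share the per-channel background offset but carry independent
    noise realizations drawn from ``params.seed``.  The ground truth is the
    analytic mean of the noiseless emission profile over the pixels whose
    centers lie inside the generating well circle — exactly the quantity the
    quantifier estimates after background subtraction with the true ROI.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    base = np.empty(shape + (3,), dtype=float)
    for ch in range(3):
        base[:, :, ch] = params.background_rgb[ch]

    background = np.empty_like(base, dtype=np.uint8)
    signal = np.empty_like(base, dtype=np.uint8)
    emission = _emission_profile(params)
    for ch in range(3):
        background[:, :, ch] = _quantize(base[:, :, ch], rng, params.noise_scale)
    for ch in range(3):
        channel = base[:, :, ch] + (emission if ch == 2 else 0.0)
        signal[:, :, ch] = _quantize(channel, rng, params.noise_scale)

    yy, xx = np.mgrid[0 : params.height, 0 : params.width].astype(float)
    inside = (xx - params.center_x) ** 2 + (yy - params.center_y) ** 2 <= params.well_radius**2
    truth = float(emission[inside].mean())
    return SCLImage(background), SCLImage(signal), truth


@dataclass(frozen=True)
class FixtureSet:
    """The canonical study conditions used across tests and examples."""

    drives: tuple[SourceDrive, ...]
    expected_displacement_nm: tuple[float, ...]
    sonication_times_s: tuple[float, ...]
    medium: MediumProperties
    geometry: WellGeometry


def fixtures() -> FixtureSet:
    """Parameter fixtures: three 1 MHz continuous-wave drive levels
    (0.30 / 0.45 / 0.60 W/cm^2) with the reference water well geometry and the
    six-point sonication-time grid."""
    medium = MediumProperties()
    geometry = WellGeometry()
    drives = tuple(
        SourceDrive.from_practical(p, medium=medium, geometry=geometry)
        for p in DRIVE_POWERS_W_CM2
    )
    return FixtureSet(
        drives=drives,
        expected_displacement_nm=REFERENCE_DISPLACEMENT_NM,
        sonication_times_s=SONICATION_TIMES_S,
        medium=medium,
        geometry=geometry,
    )


def reference_fields() -> dict[str, dict[float, Column1D]]:
    """Closed-form 1-D column fields for three canonical top conditions.

    Keys: ``matched`` (top impedance rho*c — single travelling wave),
    ``rigid`` (infinite impedance — pressure antinode at the surface) and
    ``air`` (the water/air impedance, nearly pressure-release).  Each maps
    input power density [W/cm^2] to a :class:`Column1D`.
    """
    fix = fixtures()
    acoustics = complex_acoustics(fix.medium, fix.drives[0].frequency)
    tops = {
        "matched": fix.medium.characteristic_impedance,
        "rigid": np.inf,
        "air": 4.017e2,
    }
    out: dict[str, dict[float, Column1D]] = {}
    for name, z_top in tops.items():
        out[name] = {
            power: analytic_1d_column(
                acoustics, drive, z_top, fix.geometry.solution_height
            )
            for power, drive in zip(DRIVE_POWERS_W_CM2, fix.drives)
        }
    return out
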