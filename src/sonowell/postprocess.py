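"""Intensity fields, plane averages and reporting summaries.

From the complex pressure ``p`` the particle velocity follows from the
linearized momentum balance under the ``exp(+i*omega*t)`` convention,

    v = -grad(p) / (i * omega * rho_c),

and the time-averaged acoustic intensity vector (the quantity plotted as
"acoustic density" in W/cm^2 by ultrasound exposimetry studies) is

    I = 1/2 * Re(p * conj(v)).

Reported quantities mirror the standard well-characterization layout:
spatial averages of |p| and |I| over three vertical planes (through the
axis, at half radius, and 0.1 um inside the wall), four horizontal planes,
and the whole volume, plus the global extrema of the phase-zero
instantaneous pressure and the peak intensity magnitude.

Averaging conventions: vertical planes are planar sections, averaged with
uniform (y, z) area weighting; horizontal planes are disks averaged with
the polar area element; the volume average uses the axisymmetric volume
element (proportional to the radius).  All quadratures are fixed
Gauss-Legendre tensor grids whose resolution gives several points per
finite element; doubling the resolution is the built-in self-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import DerivedAcoustics, WellGeometry, W_PER_CM2
from .solver import PressureField

__all__ = [
    "PlaneSpec",
    "IntensityField",
    "FieldSummary",
    "EnergyBalance",
    "particle_velocity",
    "intensity",
    "plane_average",
    "summarize",
    "energy_balance",
    "WALL_INSET",
    "HORIZONTAL_OFFSETS",
]

#: offset of the "wall" vertical plane from the lateral surface [m]
WALL_INSET = 1.0e-7

#: default horizontal reporting planes [m]: bottom, ~quarter height,
#: ~three-quarter height, just below the free surface
HORIZONTAL_OFFSETS = (0.0, 2.5e-3, 7.5e-3, 10.7e-3)


@dataclass(frozen=True)
class PlaneSpec:
    """A reporting region: a vertical plane, a horizontal plane, or the volume.

    ``offset`` is the x-position of a vertical plane or the height of a
    horizontal plane [m]; it is ignored for ``orientation='volume'``.
    """

    orientation: str
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal", "volume"):
            raise ValueError("orientation must be vertical, horizontal or volume")

    def validate(self, geometry: WellGeometry) -> None:
        if self.orientation == "vertical" and not (
            0.0 <= self.offset < geometry.basis_radius
        ):
            raise ValueError("vertical plane offset outside the well radius")
        if self.orientation == "horizontal" and not (
            0.0 <= self.offset <= geometry.solution_height
        ):
            raise ValueError("horizontal plane offset outside the solution height")


class IntensityField:
    """Particle velocity and time-averaged intensity derived from a pressure field.

    Provides vectorized point evaluation (``velocity``, ``vector``,
    ``magnitude``) plus nodal arrays for export.
    """

    def __init__(self, field: PressureField, acoustics: DerivedAcoustics | None = None):
        self.field = field
        self.acoustics = acoustics or field.acoustics
        self._iwrho = 1j * self.acoustics.angular_frequency * self.acoustics.complex_density

    def velocity(self, rho, z):
        """Complex particle velocity components (v_rho, v_z) [m/s]."""
        dpdr, dpdz = self.field.gradient(rho, z)
        return -dpdr / self._iwrho, -dpdz / self._iwrho

    def vector(self, rho, z):
        """Time-averaged intensity components (I_rho, I_z) [W/m^2]."""
        p = self.field.evaluate(rho, z)
        vr, vz = self.velocity(rho, z)
        return 0.5 * np.real(p * np.conj(vr)), 0.5 * np.real(p * np.conj(vz))

    def magnitude(self, rho, z):
        """Euclidean norm of the time-averaged intensity vector [W/m^2]."""
        ir, iz = self.vector(rho, z)
        return np.hypot(ir, iz)

    def plane_wave_equivalent(self, rho, z):
        """|p|^2 / (2 rho c): the plane-wave-equivalent intensity [W/m^2].

        Exposed as the alternative scalar intensity measure; coincides with
        ``magnitude`` only for a pure lossless travelling wave.
        """
        m = self.acoustics.medium
        return np.abs(self.field.evaluate(rho, z)) ** 2 / (2.0 * m.density * m.sound_speed)

    def nodal(self):
        """Nodal (v_rho, v_z, I_rho, I_z, |I|) arrays on the mesh nodes."""
        rr, zz = self.field.mesh.node_coordinates()
        vr, vz = self.velocity(rr, zz)
        ir, iz = self.vector(rr, zz)
        return vr, vz, ir, iz, np.hypot(ir, iz)


def particle_velocity(field: PressureField, acoustics: DerivedAcoustics | None = None):
    """Nodal complex particle velocity (v_rho, v_z) on the mesh."""
    intens = IntensityField(field, acoustics)
    rr, zz = field.mesh.node_coordinates()
    return intens.velocity(rr, zz)


def intensity(field: PressureField, acoustics: DerivedAcoustics | None = None) -> IntensityField:
    """Build the :class:`IntensityField` of a solved pressure field."""
    return IntensityField(field, acoustics)


def _gauss_nodes(a: float, b: float, n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def plane_average(
    quantity,
    plane: PlaneSpec,
    geometry: WellGeometry,
    resolution: int = 320,
) -> float:
    """Average a scalar field ``quantity(rho, z)`` over a plane or the volume.

    * vertical plane at ``x0``: uniform average over the rectangular section
      {|y| <= sqrt(r^2 - x0^2), 0 <= z <= H}, sampling the axisymmetric field
      at radius sqrt(x0^2 + y^2);
    * horizontal plane at ``z0``: disk average, polar area element;
    * volume: average weighted by the axisymmetric volume element.

    ``resolution`` is the number of Gauss-Legendre points per direction.
    """
    plane.validate(geometry)
    r, h = geometry.basis_radius, geometry.solution_height
    if plane.orientation == "horizontal":
        xr, wr = _gauss_nodes(0.0, r, resolution)
        vals = quantity(xr, np.full_like(xr, plane.offset))
        return float((vals * xr * wr).sum() / (xr * wr).sum())
    if plane.orientation == "volume":
        xr, wr = _gauss_nodes(0.0, r, resolution)
        xz, wz = _gauss_nodes(0.0, h, resolution)
        RR, ZZ = np.meshgrid(xr, xz, indexing="ij")
        W = np.outer(xr * wr, wz)
        vals = quantity(RR, ZZ)
        return float((vals * W).sum() / W.sum())
    # vertical: exploit the y -> -y symmetry and integrate the upper half
    x0 = plane.offset
    half_chord = np.sqrt(max(r**2 - x0**2, 0.0))
    if half_chord <= 0.0:
        raise ValueError("vertical plane degenerates to a line at the wall")
    xy, wy = _gauss_nodes(0.0, half_chord, resolution)
    xz, wz = _gauss_nodes(0.0, h, resolution)
    YY, ZZ = np.meshgrid(xy, xz, indexing="ij")
    W = np.outer(wy, wz)
    vals = quantity(np.sqrt(x0**2 + YY**2), ZZ)
    return float((vals * W).sum() / W.sum())


@dataclass
class FieldSummary:
    """Plane/volume averages and global peaks of one solved configuration.

    All values are SI (Pa, W/m^2); :meth:`to_frame` renders the practical
    MPa / W/cm^2 table.  Vertical-plane keys: ``central``, ``half_radius``,
    ``wall``; ``volume`` is the whole-solution average.
    """

    input_power_density: float
    pressure_avg: dict = field(default_factory=dict)
    intensity_avg: dict = field(default_factory=dict)
    horizontal_pressure_avg: dict = field(default_factory=dict)
    horizontal_intensity_avg: dict = field(default_factory=dict)
    peak_intensity: float = 0.0
    max_pressure_phase0: float = 0.0
    min_pressure_phase0: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """One-column table in the units conventionally printed (W/cm^2, MPa)."""
        rows = {}
        for key in ("central", "half_radius", "wall", "volume"):
            rows[f"density_avg_{key}_W_per_cm2"] = self.intensity_avg[key] / W_PER_CM2
        for key in ("central", "half_radius", "wall"):
            rows[f"pressure_ampl_avg_{key}_MPa"] = self.pressure_avg[key] / 1e6
        rows["pressure_ampl_avg_volume_MPa"] = self.pressure_avg["volume"] / 1e6
        rows["peak_density_W_per_cm2"] = self.peak_intensity / W_PER_CM2
        rows["max_pressure_MPa"] = self.max_pressure_phase0 / 1e6
        rows["min_pressure_MPa"] = self.min_pressure_phase0 / 1e6
        name = f"{self.input_power_density / W_PER_CM2:g} W/cm2"
        return pd.DataFrame({name: rows})


def summarize(
    field_: PressureField,
    intensity_: IntensityField,
    geometry: WellGeometry,
    horizontal_offsets=HORIZONTAL_OFFSETS,
    resolution: int = 320,
    peak_resolution: int = 500,
) -> FieldSummary:
    """Compute the full reporting summary of one solved drive condition.

    Extrema of the instantaneous pressure are taken at the source phase where
    the bottom displacement is real and positive, i.e. as max/min of Re(p).
    Peaks are searched on a dense uniform sampling grid of ``peak_resolution``
    points per direction (peaks of a standing-wave field are grid-sensitive;
    the resolution used is part of the reported definition).
    """
    r = geometry.basis_radius
    vertical = {
        "central": 0.0,
        "half_radius": r / 2.0,
        "wall": r - WALL_INSET,
    }
    amp = field_.amplitude
    mag = intensity_.magnitude
    summary = FieldSummary(input_power_density=field_.drive.input_power_density)
    for key, x0 in vertical.items():
        spec = PlaneSpec("vertical", x0)
        summary.pressure_avg[key] = plane_average(amp, spec, geometry, resolution)
        summary.intensity_avg[key] = plane_average(mag, spec, geometry, resolution)
    vol = PlaneSpec("volume")
    summary.pressure_avg["volume"] = plane_average(amp, vol, geometry, resolution)
    summary.intensity_avg["volume"] = plane_average(mag, vol, geometry, resolution)
    for z0 in horizontal_offsets:
        spec = PlaneSpec("horizontal", z0)
        summary.horizontal_pressure_avg[z0] = plane_average(amp, spec, geometry, resolution)
        summary.horizontal_intensity_avg[z0] = plane_average(mag, spec, geometry, resolution)

    rho = np.linspace(0.0, r, peak_resolution)
    z = np.linspace(0.0, geometry.solution_height, peak_resolution)
    RR, ZZ = np.meshgrid(rho, z, indexing="ij")
    p_re = np.real(field_.evaluate(RR, ZZ))
    summary.max_pressure_phase0 = float(p_re.max())
    summary.min_pressure_phase0 = float(p_re.min())
    summary.peak_intensity = float(mag(RR, ZZ).max())
    return summary


@dataclass(frozen=True)
class EnergyBalance:
    """Time-averaged power bookkeeping of a solved field [W].

    ``power_in_bottom`` enters through the driven base; it leaves through the
    impedance walls (``power_out_lateral`` + ``power_out_top``) or is lost to
    viscous dissipation in the volume.  ``relative_imbalance`` is the residual
    of that balance normalized by the input — a pure discretization error.
    """

    power_in_bottom: float
    power_out_lateral: float
    power_out_top: float
    dissipated: float
    @property
    def relative_imbalance(self) -> float:
        out = self.power_out_lateral + self.power_out_top + self.dissipated
        return abs(self.power_in_bottom - out) / abs(self.power_in_bottom)


def energy_balance(field_: PressureField, resolution: int = 400) -> EnergyBalance:
    """Check conservation of time-averaged acoustic power.

    Every term is measured from the recovered finite-element field, so the
    residual of the balance is a genuine discretization-error indicator (the
    alternative bookkeeping — taking the wall fluxes from the boundary data
    ``|p|**2/(2Z)`` — closes identically for any Galerkin solution and checks
    nothing).  The viscous dissipation density follows from the divergence of
    the intensity vector under the lossy Helmholtz equation:
    ``D = (1/(2 omega)) * (Im(beta) |grad p|^2 - Im(beta k^2) |p|^2)`` with
    ``beta = 1/rho_c``; for the equivalent-fluid water model ``beta k^2`` is
    real and ``D = delta |grad p|^2 / (2 rho c^2)``.
    """
    mesh = field_.mesh
    ac = field_.acoustics
    intens = IntensityField(field_)
    omega = ac.angular_frequency
    beta = 1.0 / ac.complex_density
    betak2 = beta * ac.wavenumber**2

    xr, wr = _gauss_nodes(0.0, mesh.radius, resolution)
    xz, wz = _gauss_nodes(0.0, mesh.height, resolution)

    _, iz_bottom = intens.vector(xr, np.zeros_like(xr))
    power_in = 2.0 * np.pi * float((iz_bottom * xr * wr).sum())
    _, iz_top = intens.vector(xr, np.full_like(xr, mesh.height))
    power_top = 2.0 * np.pi * float((iz_top * xr * wr).sum())
    ir_lat, _ = intens.vector(np.full_like(xz, mesh.radius), xz)
    power_lat = 2.0 * np.pi * mesh.radius * float((ir_lat * wz).sum())

    RR, ZZ = np.meshgrid(xr, xz, indexing="ij")
    W = np.outer(xr * wr, wz)
    dpdr, dpdz = field_.gradient(RR, ZZ)
    grad2 = np.abs(dpdr) ** 2 + np.abs(dpdz) ** 2
    p2 = np.abs(field_.evaluate(RR, ZZ)) ** 2
    density = (np.imag(beta) * grad2 - np.imag(betak2) * p2) / (2.0 * omega)
    dissipated = 2.0 * np.pi * float((density * W).sum())

    return EnergyBalance(
        power_in_bottom=power_in,
        power_out_lateral=power_lat,
        power_out_top=power_top,
        dissipated=dissipated,
    )
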