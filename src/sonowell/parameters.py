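"""Physical parameters of the sonicated-well model and their derived quantities.

The model describes a cylindrical volume of water sitting in one well of a
polystyrene multiwell plate, driven from below by a planar ultrasound
transducer through the well base.  Everything downstream (the Helmholtz
solve, the intensity post-processing) consumes the derived quantities
computed here:

* the sound diffusivity ``delta = (4/3*mu + mu_b)/rho`` that encodes viscous
  damping of the wave,
* the complex speed of sound ``c_c = c*(1 + i*omega*delta/c**2)**0.5`` and the
  complex density ``rho_c = rho*c**2/c_c**2`` of the equivalent-fluid model,
* the complex wavenumber ``k_eq = omega/c_c``,
* the intensity ``I_0 = I_input*exp(-2*alpha*t)`` transmitted through the
  polystyrene base of thickness ``t`` and attenuation ``alpha``, and
* the bottom-wall displacement amplitude ``L_D = sqrt(2*I_0/(rho*c*omega**2))``
  that drives the acoustic field.

Time convention
---------------
All phasors carry ``exp(+i*omega*t)``.  Under this convention the impedance
boundary flux is ``-p*i*omega/Z``, the particle velocity is
``v = -grad(p)/(i*omega*rho_c)``, and the outgoing wave ``exp(-i*k_eq*z)``
decays in its propagation direction because ``Im(k_eq) < 0`` (principal
square-root branch).

Units: SI throughout internally.  Constructors accept the mixed practical
units common in the ultrasound literature (W/cm^2, cm^-1, mm, nm) via the
``*_from_practical`` helpers and the configuration loader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MediumProperties",
    "DerivedAcoustics",
    "BoundaryImpedances",
    "WellGeometry",
    "SourceDrive",
    "sound_diffusivity",
    "complex_acoustics",
    "transmitted_intensity",
    "displacement_amplitude",
    "W_PER_CM2",
    "PER_CM",
]

#: multiply a W/cm^2 value by this to obtain W/m^2
W_PER_CM2 = 1.0e4
#: multiply a cm^-1 value by this to obtain m^-1
PER_CM = 1.0e2


class InvalidParameterError(ValueError):
    """A physical parameter violates its validity domain."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidParameterError(message)


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic constants of the propagation medium (default: water, 298.15 K).

    Parameters
    ----------
    density : float
        Mass density ``rho`` [kg/m^3].
    dynamic_viscosity : float
        Dynamic (shear) viscosity ``mu`` [Pa s].
    bulk_viscosity : float
        Bulk viscosity ``mu_b`` [Pa s].
    sound_speed : float
        Small-signal sound speed ``c`` [m/s].
    """

    density: float = 998.0
    dynamic_viscosity: float = 0.890e-3
    bulk_viscosity: float = 2.485e-3
    sound_speed: float = 1497.0

    def __post_init__(self) -> None:
        _require(self.density > 0, "density must be > 0")
        _require(self.dynamic_viscosity >= 0, "dynamic_viscosity must be >= 0")
        _require(self.bulk_viscosity >= 0, "bulk_viscosity must be >= 0")
        _require(self.sound_speed > 0, "sound_speed must be > 0")

    @property
    def characteristic_impedance(self) -> float:
        """``rho*c`` [Pa s/m] — the plane-wave impedance of the medium."""
        return self.density * self.sound_speed


@dataclass(frozen=True)
class BoundaryImpedances:
    """Specific acoustic impedances of the well walls (defaults: polystyrene, air)."""

    lateral_impedance: float = 2.5e6
    top_impedance: float = 4.017e2

    def __post_init__(self) -> None:
        _require(self.lateral_impedance > 0, "lateral_impedance must be > 0")
        _require(self.top_impedance > 0, "top_impedance must be > 0")


@dataclass(frozen=True)
class WellGeometry:
    """Cylindrical water column geometry: radius, solution height, base thickness [m]."""

    basis_radius: float = 7.950e-3
    solution_height: float = 10.78e-3
    base_thickness: float = 1.3e-3

    def __post_init__(self) -> None:
        _require(self.basis_radius > 0, "basis_radius must be > 0")
        _require(self.solution_height > 0, "solution_height must be > 0")
        _require(self.base_thickness > 0, "base_thickness must be > 0")


def sound_diffusivity(medium: MediumProperties) -> float:
    """Sound diffusivity ``delta = (4/3*mu + mu_b)/rho`` [m^2/s].

    This is the viscous-loss parameter of the equivalent-fluid model; it
    vanishes in the lossless limit ``mu = mu_b = 0``.
    """
    return (4.0 / 3.0 * medium.dynamic_viscosity + medium.bulk_viscosity) / medium.density


@dataclass(frozen=True)
class DerivedAcoustics:
    """Complex-valued acoustic quantities derived from the medium at one frequency.

    Built by :func:`complex_acoustics`; all fields follow the ``exp(+i*omega*t)``
    convention documented in the module docstring.
    """

    angular_frequency: float
    sound_diffusivity: float
    complex_sound_speed: complex
    complex_density: complex
    wavenumber: complex
    medium: MediumProperties = field(repr=False)

    @property
    def frequency(self) -> float:
        return self.angular_frequency / (2.0 * math.pi)

    @property
    def wavelength(self) -> float:
        """Real wavelength ``c/f`` [m] used for mesh sizing."""
        return self.medium.sound_speed / self.frequency


def complex_acoustics(medium: MediumProperties, frequency: float) -> DerivedAcoustics:
    """Derive complex sound speed, density and wavenumber at ``frequency`` [Hz].

    ``c_c = c*(1 + i*omega*delta/c**2)**0.5`` (principal branch),
    ``rho_c = rho*c**2/c_c**2`` and ``k_eq = omega/c_c``; the identity
    ``rho_c*c_c**2 == rho*c**2`` holds by construction.
    """
    _require(frequency > 0, "frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    delta = sound_diffusivity(medium)
    c = medium.sound_speed
    c_c = c * complex(1.0, omega * delta / c**2) ** 0.5
    rho_c = medium.density * c**2 / c_c**2
    k_eq = omega / c_c
    return DerivedAcoustics(
        angular_frequency=omega,
        sound_diffusivity=delta,
        complex_sound_speed=c_c,
        complex_density=rho_c,
        wavenumber=k_eq,
        medium=medium,
    )


def transmitted_intensity(input_intensity: float, attenuation: float, thickness: float) -> float:
    """Intensity transmitted through the well base: ``I_0 = I_input*exp(-2*alpha*t)``.

    Parameters are in SI: ``input_intensity`` [W/m^2], ``attenuation`` [1/m],
    ``thickness`` [m].
    """
    _require(input_intensity >= 0, "input_intensity must be >= 0")
    _require(attenuation >= 0, "attenuation must be >= 0")
    _require(thickness >= 0, "thickness must be >= 0")
    return input_intensity * math.exp(-2.0 * attenuation * thickness)


def displacement_amplitude(transmitted: float, medium: MediumProperties, omega: float) -> float:
    """Bottom-wall displacement amplitude ``L_D = sqrt(2*I_0/(rho*c*omega**2))`` [m].

    Inverts the plane-wave intensity relation ``I_0 = 1/2*rho*c*omega**2*L_D**2``
    of a boundary oscillating harmonically with amplitude ``L_D``.
    """
    _require(transmitted >= 0, "transmitted intensity must be >= 0")
    _require(omega > 0, "omega must be > 0")
    return math.sqrt(2.0 * transmitted / (medium.density * medium.sound_speed * omega**2))


@dataclass(frozen=True)
class SourceDrive:
    """Transducer drive: frequency, input power density and the derived source terms.

    Use :meth:`from_input_power` to build one from the practically quoted
    quantities (power density in W/cm^2, attenuation in cm^-1).
    """

    frequency: float
    input_power_density: float
    attenuation_coefficient: float
    transmitted_intensity: float
    displacement_amplitude: float

    def __post_init__(self) -> None:
        _require(self.frequency > 0, "frequency must be > 0")
        _require(self.input_power_density >= 0, "input_power_density must be >= 0")
        _require(
            self.transmitted_intensity <= self.input_power_density * (1 + 1e-12),
            "transmitted intensity cannot exceed the input",
        )
        _require(self.displacement_amplitude >= 0, "displacement_amplitude must be >= 0")

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency

    @classmethod
    def from_input_power(
        cls,
        input_power_density: float,
        medium: MediumProperties | None = None,
        geometry: WellGeometry | None = None,
        frequency: float = 1.0e6,
        attenuation_coefficient: float = 0.108 * PER_CM,
    ) -> "SourceDrive":
        """Build a drive from SI inputs (``input_power_density`` in W/m^2)."""
        medium = medium or MediumProperties()
        geometry = geometry or WellGeometry()
        omega = 2.0 * math.pi * frequency
        i0 = transmitted_intensity(
            input_power_density, attenuation_coefficient, geometry.base_thickness
        )
        ld = displacement_amplitude(i0, medium, omega)
        return cls(
            frequency=frequency,
            input_power_density=input_power_density,
            attenuation_coefficient=attenuation_coefficient,
            transmitted_intensity=i0,
            displacement_amplitude=ld,
        )

    @classmethod
    def from_practical(
        cls,
        input_power_w_per_cm2: float,
        medium: MediumProperties | None = None,
        geometry: WellGeometry | None = None,
        frequency: float = 1.0e6,
        attenuation_per_cm: float = 0.108,
    ) -> "SourceDrive":
        """Build a drive from practical units (W/cm^2 and cm^-1)."""
        return cls.from_input_power(
            input_power_w_per_cm2 * W_PER_CM2,
            medium=medium,
            geometry=geometry,
            frequency=frequency,
            attenuation_coefficient=attenuation_per_cm * PER_CM,
        )
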