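"""Structured axisymmetric mesh for the cylindrical well.

The water column is a cylinder, the drive and every boundary condition are
axisymmetric, so the computational domain is the meridian rectangle
``[0, r] x [0, H]`` in (radial, axial) coordinates with ``z = 0`` at the well
bottom (transducer side).  The mesh is a uniform grid of tensor-product
Lagrange quadrilaterals (biquadratic by default; bicubic available for
validation studies where the dispersion error of quadratic elements
matters).  Element size follows the 8-to-10-elements-per-wavelength rule
customary for FEM acoustics, with the maximum size capped at one eighth of
the wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import WellGeometry

__all__ = ["AxiMesh", "build_mesh", "BOUNDARY_TAGS"]

BOUNDARY_TAGS = ("bottom", "top", "lateral", "axis")


@dataclass(frozen=True)
class AxiMesh:
    """Uniform Lagrange-element grid on the meridian rectangle of the well.

    Attributes
    ----------
    radius, height : float
        Domain extents [m]; radial coordinate in ``[0, radius]``, axial in
        ``[0, height]``.
    n_r, n_z : int
        Number of elements in the radial / axial direction.
    order : int
        Polynomial order of the tensor-product Lagrange basis (2 or 3).
    """

    radius: float
    height: float
    n_r: int
    n_z: int
    order: int = 2

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("mesh extents must be positive")
        if self.n_r < 1 or self.n_z < 1:
            raise ValueError("need at least one element per direction")
        if self.order not in (2, 3):
            raise ValueError("element order must be 2 or 3")

    # ---- sizes -----------------------------------------------------------
    @property
    def h_r(self) -> float:
        return self.radius / self.n_r

    @property
    def h_z(self) -> float:
        return self.height / self.n_z

    @property
    def h(self) -> float:
        """Characteristic element size: the larger of the two grid spacings."""
        return max(self.h_r, self.h_z)

    @property
    def n_elements(self) -> int:
        return self.n_r * self.n_z

    # ---- nodes -----------------------------------------------------------
    @property
    def nodes_r(self) -> int:
        """Number of node columns (``order`` nodes per element plus one)."""
        return self.order * self.n_r + 1

    @property
    def nodes_z(self) -> int:
        return self.order * self.n_z + 1

    @property
    def n_nodes(self) -> int:
        return self.nodes_r * self.nodes_z

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays (rho, z) of all node positions, radial index fastest."""
        r = np.linspace(0.0, self.radius, self.nodes_r)
        z = np.linspace(0.0, self.height, self.nodes_z)
        zz, rr = np.meshgrid(z, r, indexing="ij")
        return rr.ravel(), zz.ravel()

    def node_index(self, i_r: np.ndarray | int, i_z: np.ndarray | int):
        """Global node index from (radial, axial) node indices."""
        return np.asarray(i_z) * self.nodes_r + np.asarray(i_r)

    def local_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Local (radial, axial) node offsets of one element, a = n1d*az + ar."""
        n1d = self.order + 1
        az, ar = np.divmod(np.arange(n1d * n1d), n1d)
        return ar, az

    def element_connectivity(self) -> np.ndarray:
        """(n_elements, n_local) global node indices, local a = n1d*az + ar."""
        er = np.arange(self.n_r)
        ez = np.arange(self.n_z)
        EZ, ER = np.meshgrid(ez, er, indexing="ij")
        ar, az = self.local_nodes()
        return self.node_index(
            self.order * ER.ravel()[:, None] + ar[None, :],
            self.order * EZ.ravel()[:, None] + az[None, :],
        )

    def boundary_facets(self, tag: str) -> np.ndarray:
        """(n_facets, order+1) node indices of the line facets on one boundary.

        Tags: ``bottom`` (z=0), ``top`` (z=H), ``lateral`` (rho=r) and ``axis``
        (rho=0, the symmetry axis — no boundary condition is applied there,
        the axisymmetric weak form is naturally regular).
        """
        span = np.arange(self.order + 1)
        if tag == "bottom":
            e = np.arange(self.n_r)
            return self.node_index(self.order * e[:, None] + span, 0)
        if tag == "top":
            e = np.arange(self.n_r)
            return self.node_index(self.order * e[:, None] + span, self.nodes_z - 1)
        if tag == "lateral":
            e = np.arange(self.n_z)
            return self.node_index(self.nodes_r - 1, self.order * e[:, None] + span)
        if tag == "axis":
            e = np.arange(self.n_z)
            return self.node_index(0, self.order * e[:, None] + span)
        raise ValueError(f"unknown boundary tag {tag!r}; expected one of {BOUNDARY_TAGS}")

    def locate(self, rho: np.ndarray, z: np.ndarray):
        """Element indices and local (xi, eta) in [-1,1]^2 for physical points.

        Points are clipped to the closed domain, so evaluation on the boundary
        is well defined.
        """
        rho = np.clip(np.asarray(rho, dtype=float), 0.0, self.radius)
        z = np.clip(np.asarray(z, dtype=float), 0.0, self.height)
        er = np.minimum((rho / self.h_r).astype(int), self.n_r - 1)
        ez = np.minimum((z / self.h_z).astype(int), self.n_z - 1)
        xi = 2.0 * (rho - (er + 0.5) * self.h_r) / self.h_r
        eta = 2.0 * (z - (ez + 0.5) * self.h_z) / self.h_z
        return er, ez, xi, eta


def build_mesh(
    geometry: WellGeometry,
    frequency: float,
    sound_speed: float,
    refinement: float = 1.0,
    order: int = 2,
) -> AxiMesh:
    """Mesh the well at or below one eighth of a wavelength per element.

    ``refinement`` divides the target element size; 1.0 gives the coarsest
    admissible grid (h <= lambda/8), 2.0 exactly halves its spacings, and so
    on (the base element counts are scaled, so integer refinements nest).
    """
    if refinement < 1.0:
        raise ValueError("refinement must be >= 1")
    if frequency <= 0 or sound_speed <= 0:
        raise ValueError("frequency and sound speed must be positive")
    wavelength = sound_speed / frequency
    h_max = wavelength / 8.0
    n_r = max(1, math.ceil(refinement * math.ceil(geometry.basis_radius / h_max)))
    n_z = max(1, math.ceil(refinement * math.ceil(geometry.solution_height / h_max)))
    return AxiMesh(
        radius=geometry.basis_radius,
        height=geometry.solution_height,
        n_r=n_r,
        n_z=n_z,
        order=order,
    )
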