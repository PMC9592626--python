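"""Finite-element solution of the lossy Helmholtz problem in the well.

Governing equation (frequency domain, ``exp(+i*omega*t)`` phasors)::

    div( -(1/rho_c) * grad p ) - k_eq**2 * p / rho_c = 0

on the axisymmetric meridian rectangle, with flux boundary conditions

* lateral wall (rho = r):   n.((1/rho_c) grad p) = -i*omega*p / Z_ps
* top surface (z = H):      n.((1/rho_c) grad p) = -i*omega*p / Z_air
* bottom (z = 0):           n.((1/rho_c) grad p) = (i*omega)**2 * L_D
* symmetry axis (rho = 0):  natural (zero-flux) condition; the axisymmetric
  weak form with area element ``rho dr dz`` is regular there.

The weak form is assembled with tensor-product Lagrange elements
(biquadratic by default) on the structured grid of
:class:`~sonowell.mesh.AxiMesh` and solved by sparse direct factorization;
the monopole and dipole volume sources of the general pressure acoustics
formulation are identically zero here (no source inside the fluid).  The
problem is linear, so the pressure field is proportional to the bottom
displacement amplitude ``L_D`` and every intensity-derived quantity to
``L_D**2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import AxiMesh, build_mesh
from .parameters import (
    BoundaryImpedances,
    DerivedAcoustics,
    MediumProperties,
    SourceDrive,
    WellGeometry,
    complex_acoustics,
)

__all__ = [
    "SolverConfig",
    "PressureField",
    "solve",
    "simulate",
    "analytic_1d_column",
    "Column1D",
    "SingularSystemError",
]


class SingularSystemError(RuntimeError):
    """The assembled linear system is singular or produced a non-finite solution."""


@dataclass(frozen=True)
class SolverConfig:
    """Discretization and solver options.

    The monopole (``Q_m``) and dipole (``q_d``) volume sources exist in the
    general pressure-acoustics formulation but are fixed to zero for this
    model; non-zero values are rejected.  ``lateral_condition`` switches the
    lateral wall between the physical impedance condition and an idealized
    sound-hard (rigid) wall, the latter used for validation against the 1-D
    column solution.  ``element_order`` selects quadratic (default) or cubic
    Lagrange elements; cubic suppresses the residual dispersion error of the
    quadratic basis and is used in convergence/oracle studies.
    """

    refinement: float = 1.0
    linear_solver: str = "direct"
    monopole_source: float = 0.0
    dipole_source: float = 0.0
    lateral_condition: str = "impedance"
    element_order: int = 2

    def __post_init__(self) -> None:
        if self.monopole_source != 0.0 or self.dipole_source != 0.0:
            raise ValueError("volume sources are fixed to zero in this model")
        if self.linear_solver not in ("direct",):
            raise ValueError("only the direct sparse solver is supported")
        if self.lateral_condition not in ("impedance", "rigid"):
            raise ValueError("lateral_condition must be 'impedance' or 'rigid'")
        if self.refinement < 1.0:
            raise ValueError("refinement must be >= 1")
        if self.element_order not in (2, 3):
            raise ValueError("element_order must be 2 or 3")


# --- Lagrange shape functions --------------------------------------------


def _lagrange_nodes(order: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, order + 1)


def _shape1(xi, order: int) -> np.ndarray:
    """1-D Lagrange basis of given order at xi, stacked on the last axis."""
    xs = _lagrange_nodes(order)
    xi = np.asarray(xi, dtype=float)
    out = np.ones(xi.shape + (order + 1,))
    for j in range(order + 1):
        for m in range(order + 1):
            if m != j:
                out[..., j] *= (xi - xs[m]) / (xs[j] - xs[m])
    return out


def _dshape1(xi, order: int) -> np.ndarray:
    """Derivatives of the 1-D Lagrange basis at xi."""
    xs = _lagrange_nodes(order)
    xi = np.asarray(xi, dtype=float)
    out = np.zeros(xi.shape + (order + 1,))
    for j in range(order + 1):
        for m in range(order + 1):
            if m == j:
                continue
            term = np.ones_like(xi) / (xs[j] - xs[m])
            for l in range(order + 1):
                if l != j and l != m:
                    term = term * (xi - xs[l]) / (xs[j] - xs[l])
            out[..., j] += term
    return out


def _gauss(order: int):
    """Gauss rule exactly integrating the rho-weighted element integrands."""
    return np.polynomial.legendre.leggauss(order + 2)


def _reference_matrices(h_r: float, h_z: float, order: int):
    """Reference stiffness/mass split into constant and xi-linear parts.

    The radial weight of the axisymmetric measure is
    ``rho = rho_center + (h_r/2)*xi``, so each element matrix is
    ``rho_center * M_const + (h_r/2) * M_linear`` with both parts shared by
    every element of the uniform grid.
    """
    n1d = order + 1
    nl = n1d * n1d
    K1 = np.zeros((nl, nl))
    K2 = np.zeros((nl, nl))
    M1 = np.zeros((nl, nl))
    M2 = np.zeros((nl, nl))
    jac = (h_r / 2.0) * (h_z / 2.0)
    gx, gw = _gauss(order)
    for xg, wx in zip(gx, gw):
        Nx, dNx = _shape1(xg, order), _dshape1(xg, order)
        for zg, wz in zip(gx, gw):
            Nz, dNz = _shape1(zg, order), _dshape1(zg, order)
            w = wx * wz * jac
            N = np.outer(Nz, Nx).ravel()
            dN_r = np.outer(Nz, dNx).ravel() * (2.0 / h_r)
            dN_z = np.outer(dNz, Nx).ravel() * (2.0 / h_z)
            grad = np.outer(dN_r, dN_r) + np.outer(dN_z, dN_z)
            mass = np.outer(N, N)
            K1 += w * grad
            K2 += w * grad * xg
            M1 += w * mass
            M2 += w * mass * xg
    return K1, K2, M1, M2


def _line_matrices(order: int):
    """1-D facet mass matrix split into constant and xi-linear parts."""
    n1d = order + 1
    B1 = np.zeros((n1d, n1d))
    B2 = np.zeros((n1d, n1d))
    v1 = np.zeros(n1d)
    v2 = np.zeros(n1d)
    gx, gw = _gauss(order)
    for xg, wx in zip(gx, gw):
        N = _shape1(xg, order)
        B1 += wx * np.outer(N, N)
        B2 += wx * np.outer(N, N) * xg
        v1 += wx * N
        v2 += wx * N * xg
    return B1, B2, v1, v2


def _boundary_mass(mesh: AxiMesh, tag: str) -> sp.csr_matrix:
    """Facet mass matrix ``int N_a N_b rho ds`` on one tagged boundary."""
    B1, B2, _, _ = _line_matrices(mesh.order)
    facets = mesh.boundary_facets(tag)
    n = facets.shape[0]
    n1d = mesh.order + 1
    if tag == "lateral":
        jac = mesh.h_z / 2.0
        weights = np.full(n, mesh.radius)
        elem = jac * (weights[:, None, None] * B1)
    elif tag in ("top", "bottom"):
        jac = mesh.h_r / 2.0
        centers = (np.arange(n) + 0.5) * mesh.h_r
        elem = jac * (centers[:, None, None] * B1 + (mesh.h_r / 2.0) * B2)
    else:
        raise ValueError(f"no boundary integral defined on tag {tag!r}")
    rows = np.repeat(facets, n1d, axis=1).ravel()
    cols = np.tile(facets, (1, n1d)).ravel()
    return sp.coo_matrix(
        (elem.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def _bottom_load(mesh: AxiMesh) -> np.ndarray:
    """Load vector ``int N_a rho ds`` over the bottom facet."""
    _, _, v1, v2 = _line_matrices(mesh.order)
    facets = mesh.boundary_facets("bottom")
    b = np.zeros(mesh.n_nodes)
    centers = (np.arange(facets.shape[0]) + 0.5) * mesh.h_r
    elem = (mesh.h_r / 2.0) * (centers[:, None] * v1 + (mesh.h_r / 2.0) * v2)
    np.add.at(b, facets.ravel(), elem.ravel())
    return b


@dataclass
class PressureField:
    """Complex nodal pressure on an :class:`AxiMesh`, with point evaluation.

    ``evaluate`` and ``gradient`` interpolate the finite-element field at
    arbitrary (rho, z) points; both are vectorized over point arrays.
    """

    mesh: AxiMesh
    p: np.ndarray
    acoustics: DerivedAcoustics
    drive: SourceDrive
    residual_norm: float = 0.0
    config: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.p.shape != (self.mesh.n_nodes,):
            raise ValueError("nodal vector does not match the mesh")
        if not np.all(np.isfinite(self.p.view(float))):
            raise SingularSystemError("pressure field contains non-finite values")

    def _interp(self, rho, z, derivatives: bool):
        mesh = self.mesh
        order = mesh.order
        er, ez, xi, eta = mesh.locate(rho, z)
        ar, az = mesh.local_nodes()
        gi = mesh.node_index(order * er[..., None] + ar, order * ez[..., None] + az)
        pg = self.p[gi]
        Nx = _shape1(xi, order)
        Nz = _shape1(eta, order)
        if not derivatives:
            return (pg * (Nz[..., az] * Nx[..., ar])).sum(axis=-1)
        dNx = _dshape1(xi, order) * (2.0 / mesh.h_r)
        dNz = _dshape1(eta, order) * (2.0 / mesh.h_z)
        dpdr = (pg * (Nz[..., az] * dNx[..., ar])).sum(axis=-1)
        dpdz = (pg * (dNz[..., az] * Nx[..., ar])).sum(axis=-1)
        return dpdr, dpdz

    def evaluate(self, rho, z) -> np.ndarray:
        """Complex pressure p(rho, z) [Pa]."""
        return self._interp(rho, z, derivatives=False)

    def gradient(self, rho, z) -> tuple[np.ndarray, np.ndarray]:
        """Complex (dp/drho, dp/dz) at the given points [Pa/m]."""
        return self._interp(rho, z, derivatives=True)

    def amplitude(self, rho, z) -> np.ndarray:
        """Pressure amplitude |p| [Pa]."""
        return np.abs(self.evaluate(rho, z))


def solve(
    mesh: AxiMesh,
    acoustics: DerivedAcoustics,
    impedances: BoundaryImpedances,
    drive: SourceDrive,
    config: SolverConfig | None = None,
) -> PressureField:
    """Assemble and solve the axisymmetric Helmholtz system on ``mesh``.

    Raises :class:`SingularSystemError` when the factorization fails or the
    solution is non-finite, and warns when the mesh is coarser than one
    eighth of the wavelength.
    """
    config = config or SolverConfig(element_order=mesh.order)
    if config.element_order != mesh.order:
        raise ValueError("config.element_order disagrees with the mesh order")
    omega = acoustics.angular_frequency
    if abs(drive.angular_frequency - omega) > 1e-9 * omega:
        raise ValueError("drive and acoustics frequencies disagree")
    if mesh.h > acoustics.wavelength / 8.0 * (1.0 + 1e-9):
        warnings.warn(
            "mesh is coarser than one eighth of the wavelength; "
            "accuracy of the acoustic solution is not guaranteed",
            stacklevel=2,
        )

    beta = 1.0 / acoustics.complex_density
    k2 = acoustics.wavenumber**2
    n1d = mesh.order + 1
    nl = n1d * n1d

    K1, K2, M1, M2 = _reference_matrices(mesh.h_r, mesh.h_z, mesh.order)
    conn = mesh.element_connectivity()
    er = np.arange(mesh.n_r)
    ez = np.arange(mesh.n_z)
    EZ, ER = np.meshgrid(ez, er, indexing="ij")
    centers = (ER.ravel() + 0.5) * mesh.h_r

    elem_K = centers[:, None, None] * K1 + (mesh.h_r / 2.0) * K2
    elem_M = centers[:, None, None] * M1 + (mesh.h_r / 2.0) * M2
    elem_A = beta * elem_K - beta * k2 * elem_M

    rows = np.repeat(conn, nl, axis=1).ravel()
    cols = np.tile(conn, (1, nl)).ravel()
    A = sp.coo_matrix(
        (elem_A.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    if config.lateral_condition == "impedance":
        A = A + (1j * omega / impedances.lateral_impedance) * _boundary_mass(mesh, "lateral")
    A = A + (1j * omega / impedances.top_impedance) * _boundary_mass(mesh, "top")

    b = (-(omega**2) * drive.displacement_amplitude) * _bottom_load(mesh).astype(complex)

    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            x = spla.spsolve(A.tocsc(), b)
        except (RuntimeError, spla.MatrixRankWarning) as exc:
            raise SingularSystemError(
                f"sparse factorization failed ({exc}); the system of size "
                f"{A.shape[0]} appears singular or severely ill-conditioned"
            ) from exc
    if not np.all(np.isfinite(x.view(float))):
        raise SingularSystemError("direct solve returned non-finite values")

    bnorm = np.linalg.norm(b)
    residual = float(np.linalg.norm(A @ x - b) / bnorm) if bnorm > 0 else 0.0
    return PressureField(
        mesh=mesh, p=x, acoustics=acoustics, drive=drive,
        residual_norm=residual, config=config,
    )


def simulate(
    drive: SourceDrive,
    medium: MediumProperties | None = None,
    geometry: WellGeometry | None = None,
    impedances: BoundaryImpedances | None = None,
    config: SolverConfig | None = None,
) -> PressureField:
    """Convenience driver: derive acoustics, build the mesh, and solve."""
    medium = medium or MediumProperties()
    geometry = geometry or WellGeometry()
    impedances = impedances or BoundaryImpedances()
    config = config or SolverConfig()
    acoustics = complex_acoustics(medium, drive.frequency)
    mesh = build_mesh(
        geometry, drive.frequency, medium.sound_speed,
        config.refinement, config.element_order,
    )
    return solve(mesh, acoustics, impedances, drive, config)


# --- 1-D column oracle ----------------------------------------------------


@dataclass(frozen=True)
class Column1D:
    """Closed-form 1-D pressure column ``p(z) = A e^{-i k z} + B e^{+i k z}``.

    Satisfies the bottom displacement condition at ``z = 0`` and an impedance
    (or rigid, ``Z_top = inf``) condition at ``z = H``; used as the analytic
    oracle for the radially uniform configuration of the FEM solve.
    """

    coeff_down: complex  # A, multiplies exp(-i k z)
    coeff_up: complex    # B, multiplies exp(+i k z)
    wavenumber: complex
    height: float

    def pressure(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        k = self.wavenumber
        return self.coeff_down * np.exp(-1j * k * z) + self.coeff_up * np.exp(1j * k * z)

    def dpressure_dz(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        k = self.wavenumber
        return (-1j * k) * self.coeff_down * np.exp(-1j * k * z) + (
            1j * k
        ) * self.coeff_up * np.exp(1j * k * z)


def analytic_1d_column(
    acoustics: DerivedAcoustics,
    drive: SourceDrive,
    top_impedance: float,
    height: float,
) -> Column1D:
    """Solve the two-wave boundary system of the 1-D driven column.

    Boundary conditions (outward normals, ``exp(+i*omega*t)``):

    * ``z = 0``: ``-(1/rho_c) dp/dz * (-1) = -omega**2 L_D`` i.e.
      ``p'(0) = rho_c * omega**2 * L_D``
    * ``z = H``: ``(1/rho_c) p'(H) = -i*omega*p(H)/Z_top``; ``Z_top = inf``
      gives the rigid cap ``p'(H) = 0``.

    Raises ``ValueError`` on a degenerate system (lossless closed-column
    resonance), advising a nonzero loss.
    """
    k = acoustics.wavenumber
    omega = acoustics.angular_frequency
    rho_c = acoustics.complex_density
    if not np.isfinite(abs(k) * height):
        raise ValueError("non-finite k*H")
    ld = drive.displacement_amplitude

    e_down = np.exp(-1j * k * height)
    e_up = np.exp(1j * k * height)
    if np.isinf(top_impedance):
        row2 = np.array([-1j * k * e_down, 1j * k * e_up])
    else:
        gamma = 1j * omega * rho_c / top_impedance
        row2 = np.array([(-1j * k + gamma) * e_down, (1j * k + gamma) * e_up])
    mat = np.array([[-1j * k, 1j * k], row2])
    rhs = np.array([rho_c * omega**2 * ld, 0.0])

    det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
    scale = np.abs(mat).max() ** 2
    if scale == 0 or abs(det) < 1e-12 * scale:
        raise ValueError(
            "degenerate column system (closed-column resonance of the lossless "
            "medium); use a medium with nonzero viscous loss"
        )
    a, b = np.linalg.solve(mat, rhs)
    return Column1D(coeff_down=a, coeff_up=b, wavenumber=k, height=height)
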