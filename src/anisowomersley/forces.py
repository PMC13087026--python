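"""Time-domain synthesis, vorticity, the radial Lamb vector and wall forces.

The Lamb vector l = u x omega is the non-conservative inertial field in the
Gromeka-Lamb decomposition of the convective acceleration.  Under the
axisymmetric straight-tube constraints (u_r = 0, d_theta = 0) it reduces to
a single radial component

    l_r = u_theta * (1/r) d_r(r u_theta) + u_z * d_r u_z
        = u_theta * omega_z - u_z * omega_theta,

with omega_theta = -d_r u_z and omega_z = (1/r) d_r(r u_theta).  Because
l_r is a product of fields, the harmonic amplitudes cannot be combined in
the complex plane: fields are first synthesised in the time domain (all
cross-harmonic interactions retained) and l_r is formed pointwise.

The endothelial load proxy integrates the transverse force density
f_r = rho * l_r over a near-wall "pillbox" control volume of thickness
delta_EC = V_EC / A_EC:

    F_EC(t) = A_EC * integral_{R - delta_EC}^{R} |f_r(r, t)| dr   [N]

Absolute magnitudes scale with the configured pressure-gradient scale G0
(through U0^2); orderings, distributions, ratios and spectra do not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constitutive import PhysicalScales, ViscosityTensor
from .solver import HarmonicSolution
from .spectral import ChebyshevGrid

#: Default number of uniform phases per cardiac cycle.  Resolves the
#: six-harmonic forcing and its quadratic products with large margin.
NT_DEFAULT = 256

#: Reference near-wall area used for the axial force proxy, m^2 (100 um^2).
A_REF_DEFAULT = 100e-12


@dataclass(frozen=True)
class FlowField:
    """Real velocity fields u(r, t*) on the radial x phase grid (one cycle)."""

    grid: ChebyshevGrid
    times: np.ndarray = field(repr=False)  # cycle fractions in [0, 1)
    uz: np.ndarray = field(repr=False)  # (N+1, Nt)
    utheta: np.ndarray = field(repr=False)
    alpha: float = 0.0


@dataclass(frozen=True)
class ECGeometry:
    """Endothelial pillbox geometry; thickness delta_EC = V_EC / A_EC."""

    A_EC: float = 100e-12  # footprint area, m^2 (100 um^2)
    V_EC: float = 100e-18  # cell volume, m^3  (100 um^3)

    def __post_init__(self) -> None:
        if self.A_EC <= 0.0 or self.V_EC <= 0.0:
            raise ValueError("A_EC and V_EC must be positive")

    @property
    def delta_EC(self) -> float:
        """Pillbox thickness, m."""
        return self.V_EC / self.A_EC


@dataclass(frozen=True)
class ECForceSeries:
    """Integrated pillbox force over one cycle, with optional diagnostics."""

    times: np.ndarray = field(repr=False)
    F_EC: np.ndarray = field(repr=False)  # N, nonnegative
    F_z_wall: np.ndarray | None = field(default=None, repr=False)  # N
    chi: np.ndarray | None = field(default=None, repr=False)
    phi: np.ndarray | None = field(default=None, repr=False)  # rad

    @property
    def F_EC_pN(self) -> np.ndarray:
        return self.F_EC * 1e12


def synthesize(solutions: Sequence[HarmonicSolution], Nt: int = NT_DEFAULT) -> FlowField:
    """Fourier synthesis u(r, t*) = Re sum_h U_h(r) e^{2 pi i h t*} on Nt phases."""
    if len(solutions) == 0:
        raise ValueError("no harmonic solutions supplied")
    grid = solutions[0].grid
    alpha = solutions[0].alpha
    for s in solutions[1:]:
        if s.grid is not grid or s.alpha != alpha:
            raise ValueError("all solutions must share one grid and alpha")
    t = np.arange(Nt) / Nt
    uz = np.zeros((grid.n, Nt))
    ut = np.zeros((grid.n, Nt))
    for s in solutions:
        phase = np.exp(1j * 2.0 * np.pi * s.h * t)
        uz += np.real(s.Uz[:, None] * phase[None, :])
        ut += np.real(s.Utheta[:, None] * phase[None, :])
    return FlowField(grid=grid, times=t, uz=uz, utheta=ut, alpha=alpha)


def vorticity(field: FlowField) -> tuple[np.ndarray, np.ndarray]:
    """(omega_theta, omega_z) matrices on the field's grid.

    omega_theta = -d_r u_z;  omega_z = (1/r) d_r(r u_theta), with the
    regular centerline limit omega_z(0) = 2 * d_r u_theta(0).
    """
    g = field.grid
    om_theta = -(g.D @ field.uz)
    r = g.nodes
    r_ut = r[:, None] * field.utheta
    om_z = np.empty_like(field.utheta)
    d_rut = g.D @ r_ut
    om_z[1:, :] = d_rut[1:, :] / r[1:, None]
    om_z[0, :] = 2.0 * (g.D @ field.utheta)[0, :]
    return om_theta, om_z


def lamb_radial(field: FlowField) -> np.ndarray:
    """Radial Lamb component l_r = u_theta omega_z - u_z omega_theta (dimensionless)."""
    om_theta, om_z = vorticity(field)
    return field.utheta * om_z - field.uz * om_theta


def ec_force(
    field: FlowField,
    scales: PhysicalScales,
    ec: ECGeometry,
    n_quad: int = 128,
) -> ECForceSeries:
    """Pillbox-integrated transverse force F_EC(t) in newtons.

    The dimensionless l_r is interpolated barycentrically onto a uniform
    sub-grid of at least 64 points inside [1 - delta_EC/R, 1] and
    integrated (composite trapezoid) with the dimensional density
    f_r = rho * l_r * U0^2 / R.
    """
    delta_star = ec.delta_EC / scales.R
    if delta_star >= 1.0:
        raise ValueError("pillbox thickness must be smaller than the vessel radius")
    if delta_star < 1e-6:
        raise ValueError("pillbox thinner than resolvable (delta_EC < 1e-6 R)")
    n_quad = max(int(n_quad), 64)
    ell = lamb_radial(field)
    r_sub = np.linspace(1.0 - delta_star, 1.0, n_quad)
    P = field.grid.interpolation_matrix(r_sub)
    ell_sub = P @ ell
    f_dim = scales.rho * scales.U0**2 / scales.R * ell_sub
    # integral over dimensional r: dr = R dr*
    F = ec.A_EC * scales.R * np.trapezoid(np.abs(f_dim), r_sub, axis=0)
    return ECForceSeries(times=field.times, F_EC=F)


def wall_traction(
    field: FlowField, tensor: ViscosityTensor, scales: PhysicalScales
) -> np.ndarray:
    """Axial wall shear stress tau_w(t) in Pa from the full constitutive law.

    tau_zr(R, t) = rho [nu_zz d_r u_z + nu_ztheta (d_r u_theta - u_theta/r)]
    evaluated at the wall, dimensionalised by rho nu_zz U0 / R.
    """
    g = field.grid
    s_z = (g.D @ field.uz)[-1, :]
    s_t = (g.D @ field.utheta)[-1, :] - field.utheta[-1, :]  # r* = 1 at the wall
    beta = tensor.nu_ztheta / tensor.nu_zz
    tau_star = s_z + beta * s_t
    return scales.rho * tensor.nu_zz * scales.U0 / scales.R * tau_star


def near_wall_radial_force(
    field: FlowField,
    scales: PhysicalScales,
    ec: ECGeometry,
    A_ref: float = A_REF_DEFAULT,
) -> np.ndarray:
    """Radial force proxy F_r_wall(t) in N.

    rho * l_r at the collocation point nearest the wall (last interior
    node), dimensionalised, times the reference area and pillbox depth.
    """
    ell = lamb_radial(field)[-2, :]
    f_dim = scales.rho * scales.U0**2 / scales.R * ell
    return f_dim * A_ref * ec.delta_EC


def force_ratio_angle(
    F_r_wall: np.ndarray, F_z_wall: np.ndarray, eps: float = 1e-300
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous ratio chi = |F_r|/|F_z| and vector angle phi = atan(F_r, F_z).

    Where |F_z| < eps, chi is reported as +inf (or 0 when F_r is also
    negligible) and phi saturates at +/- pi/2.
    """
    F_r = np.asarray(F_r_wall, dtype=float)
    F_z = np.asarray(F_z_wall, dtype=float)
    if F_r.shape != F_z.shape:
        raise ValueError("force series must share one time grid")
    small_z = np.abs(F_z) < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.abs(F_r) / np.abs(F_z)
    chi = np.where(small_z & (np.abs(F_r) < eps), 0.0, chi)
    chi = np.where(small_z & (np.abs(F_r) >= eps), np.inf, chi)
    phi = np.arctan2(F_r, F_z)
    return chi, phi


def endothelial_loading(
    field: FlowField,
    scales: PhysicalScales,
    ec: ECGeometry,
    tensor: ViscosityTensor,
    A_ref: float = A_REF_DEFAULT,
) -> ECForceSeries:
    """Full per-cycle series: F_EC, axial proxy F_z_wall = |tau_w| A_ref, chi, phi."""
    base = ec_force(field, scales, ec)
    tau_w = wall_traction(field, tensor, scales)
    F_z = np.abs(tau_w) * A_ref
    F_r = near_wall_radial_force(field, scales, ec, A_ref=A_ref)
    chi, phi = force_ratio_angle(F_r, F_z)
    return ECForceSeries(
        times=base.times, F_EC=base.F_EC, F_z_wall=F_z, chi=chi, phi=phi
    )
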