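"""Anisotropic Newtonian constitutive law and physical scales.

Blood in large arteries is treated as an incompressible fluid whose shear
viscosity is direction dependent: red-cell deformation and alignment make
the stress response to axial shear differ from the response to azimuthal
shear, and couple the two.  For fully developed axisymmetric pipe flow the
fourth-rank viscosity tensor collapses to a 2x2 matrix relating the two
relevant shear stresses (tau_zr, tau_thetar) to the two strain rates
(d_r u_z, d_r u_theta - u_theta/r),

    [tau_zr    ]         [nu_zz      nu_ztheta    ] [d_r u_z                  ]
    [tau_thetar] = rho * [nu_thetaz  nu_thetatheta] [d_r u_theta - u_theta / r]

The dimensionless anisotropy ratios are

    beta  = nu_ztheta / nu_zz      (axial-shear -> azimuthal-stress coupling)
    gamma = nu_thetaz / nu_zz      (azimuthal-shear -> axial-stress coupling)
    delta = nu_thetatheta / nu_zz  (azimuthal/axial viscosity ratio)

with the isotropic limit beta = gamma = 0, delta = 1.  Dissipativity is
enforced as positive-definiteness of the symmetric part of the viscosity
matrix: after normalising by nu_zz this is delta > 0 and
delta > (beta + gamma)^2 / 4.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Blood density, kg/m^3.
RHO_BLOOD = 1050.0

#: Fundamental cardiac angular frequency, rad/s (heart rate ~1.2 Hz).
OMEGA0_DEFAULT = 2.0 * np.pi * 1.2

#: Axial kinematic viscosity, m^2/s.  Calibrated so that
#: alpha = R*sqrt(OMEGA0_DEFAULT/NU_ZZ_DEFAULT) reproduces the tabulated
#: Womersley numbers of all six bundled arterial records from their printed
#: radii to two decimals (e.g. R = 0.015 m -> alpha = 22.03,
#: R = 0.002 m -> alpha = 2.94).  See docs/methods.md for the derivation.
NU_ZZ_DEFAULT = 3.4955e-6

#: Pressure-gradient amplitude scale, Pa/m.  Dimensionless results do not
#: depend on it; dimensional force magnitudes scale with G0^2.
G0_DEFAULT = 1.0


def _check_dissipative(one: float, beta: float, gamma: float, delta: float) -> None:
    """Raise unless the symmetric part of [[1, beta], [gamma, delta]]*one is PD."""
    off = 0.5 * (beta + gamma)
    sym = np.array([[1.0, off], [off, delta]]) * one
    eigs = np.linalg.eigvalsh(sym)
    if eigs[0] <= 0.0:
        raise ValueError(
            "viscosity tensor is not dissipative: symmetric part has "
            f"minimum eigenvalue {eigs[0] * 1.0:.6g} <= 0 "
            f"(requires delta > (beta+gamma)^2/4; got beta={beta}, "
            f"gamma={gamma}, delta={delta})"
        )


@dataclass(frozen=True)
class AnisotropyRatios:
    """Dimensionless viscosity ratios (beta, gamma, delta).

    Physiologically plausible exploration ranges are beta, gamma in
    [-0.1, 0.1] and delta in [0.9, 1.1]; the constructor enforces only the
    dissipativity constraint, not those soft ranges.
    """

    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.beta, self.gamma, self.delta]).all():
            raise ValueError("anisotropy ratios must be finite")
        if self.delta <= 0.0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        _check_dissipative(1.0, self.beta, self.gamma, self.delta)

    @property
    def is_isotropic(self) -> bool:
        return self.beta == 0.0 and self.gamma == 0.0 and self.delta == 1.0


@dataclass(frozen=True)
class ViscosityTensor:
    """The 2x2 kinematic viscosity matrix (entries in m^2/s)."""

    nu_zz: float
    nu_ztheta: float
    nu_thetaz: float
    nu_thetatheta: float

    def __post_init__(self) -> None:
        if self.nu_zz <= 0.0 or self.nu_thetatheta <= 0.0:
            raise ValueError("diagonal viscosities must be positive")
        _check_dissipative(
            self.nu_zz,
            self.nu_ztheta / self.nu_zz,
            self.nu_thetaz / self.nu_zz,
            self.nu_thetatheta / self.nu_zz,
        )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.nu_zz, self.nu_ztheta], [self.nu_thetaz, self.nu_thetatheta]]
        )

    @property
    def ratios(self) -> AnisotropyRatios:
        """Extract (beta, gamma, delta); inverse of :func:`tensor_from_ratios`."""
        return AnisotropyRatios(
            beta=self.nu_ztheta / self.nu_zz,
            gamma=self.nu_thetaz / self.nu_zz,
            delta=self.nu_thetatheta / self.nu_zz,
        )


def tensor_from_ratios(nu_zz: float, ratios: AnisotropyRatios) -> ViscosityTensor:
    """Build the dimensional viscosity tensor from nu_zz and (beta, gamma, delta)."""
    if nu_zz <= 0.0:
        raise ValueError(f"nu_zz must be positive, got {nu_zz}")
    return ViscosityTensor(
        nu_zz=nu_zz,
        nu_ztheta=ratios.beta * nu_zz,
        nu_thetaz=ratios.gamma * nu_zz,
        nu_thetatheta=ratios.delta * nu_zz,
    )


def shear_stress(tensor, rho, axial_strain, azimuthal_strain):
    """Shear stresses (tau_zr, tau_thetar) in Pa from the two strain rates.

    ``azimuthal_strain`` is the quantity (d_r u_theta - u_theta/r).  Inputs
    may be scalars or arrays (broadcast elementwise).
    """
    s1 = np.asarray(axial_strain, dtype=float)
    s2 = np.asarray(azimuthal_strain, dtype=float)
    if not (np.isfinite(s1).all() and np.isfinite(s2).all()):
        raise ValueError("strain rates must be finite")
    tau_zr = rho * (tensor.nu_zz * s1 + tensor.nu_ztheta * s2)
    tau_thetar = rho * (tensor.nu_thetaz * s1 + tensor.nu_thetatheta * s2)
    return tau_zr, tau_thetar


@dataclass(frozen=True)
class PhysicalScales:
    """Dimensional scales of a run.

    U0 = |G0| R^2 / (rho nu_zz) is the characteristic velocity and
    alpha = R sqrt(omega0 / nu_zz) the Womersley number; both are derived
    in the constructor and must not be supplied.
    """

    rho: float = RHO_BLOOD
    nu_zz: float = NU_ZZ_DEFAULT
    R: float = 0.015
    omega0: float = OMEGA0_DEFAULT
    G0: float = G0_DEFAULT
    U0: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("rho", "nu_zz", "R", "omega0"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.G0 == 0.0:
            raise ValueError("G0 must be nonzero")
        object.__setattr__(self, "U0", abs(self.G0) * self.R**2 / (self.rho * self.nu_zz))
        object.__setattr__(self, "alpha", self.R * np.sqrt(self.omega0 / self.nu_zz))


def scales_from_config(
    rho: float = RHO_BLOOD,
    nu_zz: float = NU_ZZ_DEFAULT,
    R: float = 0.015,
    omega0: float = OMEGA0_DEFAULT,
    G0: float = G0_DEFAULT,
) -> PhysicalScales:
    """Validated construction of :class:`PhysicalScales` from config values."""
    return PhysicalScales(rho=rho, nu_zz=nu_zz, R=R, omega0=omega0, G0=G0)


def radius_for_alpha(
    alpha: float,
    omega0: float = OMEGA0_DEFAULT,
    nu_zz: float = NU_ZZ_DEFAULT,
) -> float:
    """Vessel radius (m) whose Womersley number equals ``alpha``.

    Used when a parametric sweep varies alpha directly and a dimensional
    force conversion is requested: alpha is then interpreted as vessels of
    different calibre at the calibrated (omega0, nu_zz).
    """
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    return alpha * np.sqrt(nu_zz / omega0)
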