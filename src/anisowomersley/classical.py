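"""Closed-form isotropic Womersley solution (Bessel form), the validation oracle.

For an isotropic fluid the axial harmonic equation decouples and admits the
classical solution

    u_z(r, t) = Re[ (a / (i f alpha^2)) (1 - J0(lam r) / J0(lam)) e^{i omega t} ]

in solver nondimensionalisation, where a is the dimensionless gradient
amplitude (the classical Ghat/(i omega rho) prefactor maps to
a_h/(i f_h alpha^2) in solver units) and J0 is the order-zero Bessel
function of the first kind at complex argument.

Branch note: with the e^{+i omega t} synthesis convention used throughout
this package, substitution into i f alpha^2 U = a + L0 U requires
lam^2 = -i alpha^2, i.e. lam = e^{-i pi/4} alpha -- the textbook
i^{3/2} alpha (identical under the evenness of J0).  The opposite square
root pairs with the e^{-i omega t} convention; the real-valued velocity
field is the same classical Womersley field either way.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import jv

from .constitutive import AnisotropyRatios
from .solver import solve_harmonic
from .spectral import cgl_grid


@dataclass(frozen=True)
class ClassicalSolution:
    """Parameters of the closed-form mono-harmonic Womersley profile."""

    alpha: float
    Ghat: complex = 1.0 + 0.0j
    omega: float = 1.0  # dimensionless harmonic frequency f_h
    lam: complex = field(init=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0.0:
            raise ValueError("alpha must be positive")
        if self.omega <= 0.0:
            raise ValueError("omega must be positive")
        lam = np.exp(-1j * np.pi / 4.0) * self.alpha * np.sqrt(self.omega)
        if abs(jv(0, lam)) < 1e-290:
            raise ZeroDivisionError("J0(lam) vanishes")  # never for real alpha > 0
        object.__setattr__(self, "lam", lam)


def classical_axial_amplitude(sol: ClassicalSolution, r) -> np.ndarray:
    """Complex amplitude Uz(r) of the classical profile."""
    r = np.asarray(r, dtype=float)
    if r.size and (r.min() < 0.0 or r.max() > 1.0):
        raise ValueError("r must lie in [0, 1]")
    pref = sol.Ghat / (1j * sol.omega * sol.alpha**2)
    return pref * (1.0 - jv(0, sol.lam * r) / jv(0, sol.lam))


def classical_axial(sol: ClassicalSolution, r, t) -> np.ndarray:
    """Real axial velocity at radius r and cycle phase t (t in cycles)."""
    amp = classical_axial_amplitude(sol, r)
    t = np.asarray(t, dtype=float)
    phase = np.exp(1j * 2.0 * np.pi * sol.omega * t)
    return np.real(np.multiply.outer(amp, phase)).squeeze()


def linf_error(alpha_list: Sequence[float], N: int, n_phases: int = 16) -> float:
    """Max |spectral - classical| axial velocity over alphas, nodes and phases.

    Isotropic ratios, mono-harmonic forcing (h = 1, a = 1); the time sample
    is a uniform grid of ``n_phases`` >= 16 cycle fractions.
    """
    n_phases = max(int(n_phases), 16)
    grid = cgl_grid(N)
    iso = AnisotropyRatios()
    t = np.arange(n_phases) / n_phases
    worst = 0.0
    for alpha in alpha_list:
        num = solve_harmonic(grid, alpha, 1, iso, 1.0)
        u_num = np.real(num.Uz[:, None] * np.exp(1j * 2.0 * np.pi * t)[None, :])
        u_ref = classical_axial(ClassicalSolution(alpha=alpha), grid.nodes, t)
        worst = max(worst, float(np.abs(u_num - u_ref).max()))
    return worst
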