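"""Harmonic-by-harmonic spectral solver for anisotropic pulsatile pipe flow.

For each integer harmonic h of the driving pressure gradient the
dimensionless momentum balance is the coupled pair

    (L0 - i h alpha^2 I) Uz + beta  L1 Utheta = -a_h
    gamma L0 Uz + (delta L1 - i h alpha^2 I) Utheta = 0

for the complex nodal amplitudes (Uz, Utheta) on a Chebyshev grid, where
alpha is the Womersley number, a_h the real pressure-gradient amplitude
and (beta, gamma, delta) the anisotropy ratios.  The 2(N+1) x 2(N+1)
block system is closed by row replacement: no-slip Uz(1) = Utheta(1) = 0
at the wall, and dUz/dr(0) = 0 (symmetry) with Utheta(0) = 0 (regularity)
at the centerline.  Each harmonic is solved independently by direct
sparse LU factorisation; there is no cross-harmonic coupling.

Because the equations are linear, the azimuthal amplitude is exactly
linear in gamma (the only term that sources swirl) and every amplitude is
linear in a_h.  With beta = gamma = 0 the system decouples and Utheta
vanishes identically: swirl in this geometry is a purely constitutive
effect.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import AnisotropyRatios
from .spectral import ChebyshevGrid

#: Absolute tolerance for dimensionless-velocity invariant checks.
SOLVER_TOL = 1e-12


@dataclass(frozen=True)
class Waveform:
    """Real cosine-phase pressure-gradient amplitudes a_h, h = 0..H.

    The bundled physiological records are normalised so that a_0 = 1 (the
    velocity scale U0 is built from the steady gradient amplitude).
    Entries may be negative (sign flips of the cosine component).
    """

    amplitudes: tuple
    label: str = ""

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        if len(amps) == 0:
            raise ValueError("waveform needs at least one amplitude")
        if not np.isfinite(amps).all():
            raise ValueError("waveform amplitudes must be finite")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def H(self) -> int:
        """Maximum harmonic index."""
        return len(self.amplitudes) - 1


@dataclass(frozen=True)
class HarmonicSolution:
    """Complex radial amplitude profiles of one harmonic."""

    h: int
    alpha: float
    Uz: np.ndarray = field(repr=False)
    Utheta: np.ndarray = field(repr=False)
    grid: ChebyshevGrid = field(repr=False)

    @property
    def f_h(self) -> int:
        """Dimensionless frequency of the harmonic (= h)."""
        return self.h


def _assemble_dense(
    grid: ChebyshevGrid,
    alpha: float,
    h: int,
    ratios: AnisotropyRatios,
    a_h: float,
):
    """Dense block matrix and RHS for one harmonic, boundary rows replaced.

    Works in the grid's own floating type (complex128 for float64 grids,
    clongdouble for extended-precision grids).
    """
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    if h < 0:
        raise ValueError("harmonic index must be >= 0")
    rdt = grid.D.dtype
    cdt = np.result_type(rdt, np.complex64)
    alpha = rdt.type(alpha)
    inertia = h * alpha**2
    if not np.isfinite(inertia):
        raise OverflowError(f"h*alpha^2 overflow for h={h}, alpha={alpha}")
    n = grid.n
    eye = np.eye(n, dtype=rdt)
    Azz = grid.L0.astype(cdt) - 1j * inertia * eye
    Azt = (rdt.type(ratios.beta) * grid.L1).astype(cdt)
    Atz = (rdt.type(ratios.gamma) * grid.L0).astype(cdt)
    Att = (rdt.type(ratios.delta) * grid.L1).astype(cdt) - 1j * inertia * eye

    b = np.zeros(2 * n, dtype=cdt)
    b[:n] = -rdt.type(a_h)

    wall = n - 1
    # Axial wall row: Uz(1) = 0.
    Azz[wall, :] = 0.0
    Azt[wall, :] = 0.0
    Azz[wall, wall] = 1.0
    b[wall] = 0.0
    # Axial centerline row: dUz/dr(0) = 0.
    Azz[0, :] = grid.D[0, :]
    Azt[0, :] = 0.0
    b[0] = 0.0
    # Azimuthal wall row: Utheta(1) = 0.
    Atz[wall, :] = 0.0
    Att[wall, :] = 0.0
    Att[wall, wall] = 1.0
    b[n + wall] = 0.0
    # Azimuthal centerline row: Utheta(0) = 0.
    Atz[0, :] = 0.0
    Att[0, :] = 0.0
    Att[0, 0] = 1.0
    b[n] = 0.0

    return np.block([[Azz, Azt], [Atz, Att]]), b


def assemble_system(
    grid: ChebyshevGrid,
    alpha: float,
    h: int,
    ratios: AnisotropyRatios,
    a_h: float,
):
    """Assemble the block system for one harmonic as (CSC matrix, RHS)."""
    A, b = _assemble_dense(grid, alpha, h, ratios, a_h)
    return sp.csc_matrix(A), b


def _lu_solve_pivoted(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in A's own dtype.

    LAPACK has no extended-precision path, so extended-precision grids are
    solved with this vectorised elimination instead.
    """
    n = A.shape[0]
    A = A.copy()
    b = b.copy()
    for i in range(n - 1):
        p = i + int(np.argmax(np.abs(A[i:, i])))
        if A[p, i] == 0:
            raise np.linalg.LinAlgError("singular system")
        if p != i:
            A[[i, p]] = A[[p, i]]
            b[[i, p]] = b[[p, i]]
        m = A[i + 1 :, i] / A[i, i]
        A[i + 1 :, i + 1 :] -= np.outer(m, A[i, i + 1 :])
        b[i + 1 :] -= m * b[i]
        A[i + 1 :, i] = 0
    x = np.zeros(n, dtype=A.dtype)
    for i in range(n - 1, -1, -1):
        x[i] = (b[i] - A[i, i + 1 :] @ x[i + 1 :]) / A[i, i]
    return x


def solve_harmonic(
    grid: ChebyshevGrid,
    alpha: float,
    h: int,
    ratios: AnisotropyRatios,
    a_h: float,
) -> HarmonicSolution:
    """Solve one harmonic by direct LU factorisation.

    float64 grids use sparse LU (scipy spsolve); extended-precision grids
    use the in-package pivoted elimination.
    """
    if grid.D.dtype == np.float64:
        A, b = assemble_system(grid, alpha, h, ratios, a_h)
        with np.errstate(all="ignore"):
            x = spla.spsolve(A, b)
        if not np.isfinite(x).all():
            raise np.linalg.LinAlgError(
                f"singular or ill-conditioned system at h={h}, alpha={alpha} "
                f"(1-norm condition estimate ~{_cond_estimate(A):.3g})"
            )
    else:
        Ad, b = _assemble_dense(grid, alpha, h, ratios, a_h)
        x = _lu_solve_pivoted(Ad, b)
    n = grid.n
    return HarmonicSolution(h=h, alpha=alpha, Uz=x[:n], Utheta=x[n:], grid=grid)


def _cond_estimate(A: sp.spmatrix) -> float:
    try:
        lu = spla.splu(A.tocsc())
        onenorm = spla.norm(A, 1)
        e = np.ones(A.shape[0])
        return float(onenorm * np.abs(lu.solve(e)).max())
    except Exception:  # pragma: no cover - diagnostic path only
        return float("inf")


def solve_waveform(
    grid: ChebyshevGrid,
    alpha: float,
    ratios: AnisotropyRatios,
    waveform: Waveform,
) -> list[HarmonicSolution]:
    """Independent harmonic solutions for every amplitude of a waveform."""
    return [
        solve_harmonic(grid, alpha, h, ratios, a_h)
        for h, a_h in enumerate(waveform.amplitudes)
    ]


def solve_mono(
    grid: ChebyshevGrid, alpha: float, ratios: AnisotropyRatios
) -> HarmonicSolution:
    """Mono-harmonic convention used in parametric sweeps: h = 1, a_1 = 1."""
    return solve_harmonic(grid, alpha, 1, ratios, 1.0)


def interior_residual(sol: HarmonicSolution, ratios: AnisotropyRatios, a_h: float) -> float:
    """Relative residual of the un-replaced interior equations.

    Plugs the returned amplitudes back into the governing equations at the
    interior nodes (excluding the four boundary rows) and returns the
    max-norm residual relative to the forcing scale.
    """
    g = sol.grid
    inertia = sol.h * sol.alpha**2
    rz = (
        g.L0 @ sol.Uz
        + ratios.beta * (g.L1 @ sol.Utheta)
        - 1j * inertia * sol.Uz
        + a_h
    )
    rt = (
        ratios.gamma * (g.L0 @ sol.Uz)
        + ratios.delta * (g.L1 @ sol.Utheta)
        - 1j * inertia * sol.Utheta
    )
    interior = slice(1, g.n - 1)
    # standard relative residual: ||r|| / (||A|| ||x|| + ||b||)
    opnorm = float(np.abs(g.L0).sum(axis=1).max())
    xnorm = float(max(np.abs(sol.Uz).max(), np.abs(sol.Utheta).max()))
    scale = opnorm * xnorm + inertia * xnorm + abs(a_h)
    return float(
        max(np.abs(rz[interior]).max(), np.abs(rt[interior]).max()) / scale
    )


def solutions_to_records(solutions: Sequence[HarmonicSolution]) -> list[dict]:
    """JSON-friendly per-harmonic dump: node, Re/Im of both amplitudes."""
    out = []
    for s in solutions:
        out.append(
            {
                "h": s.h,
                "alpha": s.alpha,
                "node": s.grid.nodes.tolist(),
                "Re_Uz": s.Uz.real.tolist(),
                "Im_Uz": s.Uz.imag.tolist(),
                "Re_Utheta": s.Utheta.real.tolist(),
                "Im_Utheta": s.Utheta.imag.tolist(),
            }
        )
    return out
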