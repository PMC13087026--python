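"""Study protocols: arterial waveform registry, parametric sweeps, statistics.

Bundles the six physiological arterial pressure-gradient records (vessel
radius, Womersley number, six real cosine harmonics h = 0..5) and the
deterministic protocols built on the solver:

* mono-harmonic alpha x beta sweeps of swirl, axial vorticity, peak-swirl
  radius and near-wall transverse force (beta = gamma, delta = 1);
* grid-independence residuals against an N = 180 reference solution;
* pillbox force series per artery, their harmonic spectra, and the
  Kruskal-Wallis test of across-artery distinctness;
* waveform truncation error for choosing the harmonic cutoff.

Everything here is deterministic; rerunning a protocol bit-reproduces it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .constitutive import (
    AnisotropyRatios,
    PhysicalScales,
    radius_for_alpha,
    scales_from_config,
    tensor_from_ratios,
)
from .forces import (
    A_REF_DEFAULT,
    ECForceSeries,
    ECGeometry,
    FlowField,
    ec_force,
    lamb_radial,
    synthesize,
)
from .solver import Waveform, solve_mono, solve_waveform
from .spectral import ChebyshevGrid, cgl_grid


@dataclass(frozen=True)
class WaveformRecord:
    """One arterial segment: radius, Womersley number, six harmonics."""

    name: str
    R: float  # m
    alpha: float
    amplitudes: tuple  # a_h, h = 0..5

    @property
    def waveform(self) -> Waveform:
        return Waveform(amplitudes=self.amplitudes, label=self.name)


_REGISTRY = (
    WaveformRecord("Aortic Root", 0.015, 22.03, (1.00, 0.82, 0.54, 0.33, 0.24, 0.17)),
    WaveformRecord("Thoracic Aorta", 0.012, 17.62, (1.00, 0.76, 0.45, 0.28, 0.20, 0.12)),
    WaveformRecord("Femoral", 0.004, 5.87, (1.00, 0.58, 0.10, -0.17, 0.05, 0.04)),
    WaveformRecord("Carotid", 0.0035, 5.14, (1.00, 0.63, 0.31, 0.15, 0.10, 0.06)),
    WaveformRecord("Iliac", 0.0045, 6.61, (1.00, 0.51, 0.12, -0.11, 0.05, 0.03)),
    WaveformRecord("Brachial", 0.002, 2.94, (1.00, 0.49, 0.16, -0.05, 0.02, 0.01)),
)


def registry() -> list[WaveformRecord]:
    """The six bundled arterial records."""
    return list(_REGISTRY)


def get_record(name: str) -> WaveformRecord:
    for rec in _REGISTRY:
        if rec.name.lower() == name.lower():
            return rec
    known = ", ".join(r.name for r in _REGISTRY)
    raise KeyError(f"unknown artery {name!r}; known: {known}")


def scales_for(record: WaveformRecord, **overrides) -> PhysicalScales:
    """Physical scales of a record at the calibrated defaults (R from the table)."""
    kwargs = {"R": record.R}
    kwargs.update(overrides)
    return scales_from_config(**kwargs)


# ---------------------------------------------------------------------------
# Mono-harmonic parametric sweep (beta = gamma, delta = 1 convention)
# ---------------------------------------------------------------------------

#: Default sweep grids: resolve the swirl/vorticity peak structure without
#: excessive cells.
ALPHA_GRID_DEFAULT = tuple(np.arange(1.0, 25.0 + 1e-9, 0.5))
BETA_GRID_DEFAULT = tuple(np.arange(0.0, 0.1 + 1e-12, 0.0125))


@dataclass(frozen=True)
class SweepResult:
    """Mono-harmonic sweep observables; rows index alpha, columns beta."""

    alpha_grid: np.ndarray = field(repr=False)
    beta_grid: np.ndarray = field(repr=False)
    swirl_max: np.ndarray = field(repr=False)  # max_r |Utheta|
    vortz_max: np.ndarray = field(repr=False)  # max_r |omega_z hat|
    peak_loc: np.ndarray = field(repr=False)  # r/R of the swirl maximum
    wall_force: np.ndarray = field(repr=False)  # dimensionless near-wall max_t |l_r|
    wall_force_pN: np.ndarray = field(repr=False)  # pN at per-alpha calibrated scales

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alpha_grid):
            for j, b in enumerate(self.beta_grid):
                rows.append(
                    {
                        "alpha": a,
                        "beta": b,
                        "swirl_max": self.swirl_max[i, j],
                        "vortz_max": self.vortz_max[i, j],
                        "peak_loc_rR": self.peak_loc[i, j],
                        "wall_force_dimless": self.wall_force[i, j],
                        "wall_force_pN": self.wall_force_pN[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _refine_peak(grid: ChebyshevGrid, profile, lo=0.0, hi=1.0, tol=1e-4):
    """Locate the maximiser of |interpolant of profile| to ``tol`` resolution.

    Coarse scan of the (complex) barycentric interpolant followed by grid
    refinement around the running maximiser; returns (location, max value).
    """

    def eval_abs(targets):
        return np.abs(grid.barycentric_eval(profile, targets))

    r_best, v_best = lo, -np.inf
    r_grid = np.linspace(lo, hi, 513)
    while True:
        vals = eval_abs(r_grid)
        k = int(np.argmax(vals))
        if vals[k] > v_best:
            r_best, v_best = float(r_grid[k]), float(vals[k])
        step = r_grid[1] - r_grid[0]
        if step <= tol / 4:
            break
        r_grid = np.linspace(max(lo, r_best - 2 * step), min(hi, r_best + 2 * step), 65)
    return r_best, v_best


def _mono_cell(grid, alpha, beta, Nt=64, ec=None, A_ref=A_REF_DEFAULT):
    """Solve one sweep cell and extract the four observables."""
    ratios = AnisotropyRatios(beta=beta, gamma=beta, delta=1.0)
    sol = solve_mono(grid, alpha, ratios)
    # swirl magnitude and location via the complex interpolant
    peak_r, swirl = _refine_peak(grid, sol.Utheta)
    # axial vorticity amplitude at the nodes
    r = grid.nodes
    d_rut = grid.D @ (r * sol.Utheta)
    om_z = np.empty_like(sol.Utheta)
    om_z[1:] = d_rut[1:] / r[1:]
    om_z[0] = 2.0 * (grid.D @ sol.Utheta)[0]
    vort = float(np.abs(om_z).max())
    # near-wall transverse force: max over the cycle of |l_r| at the last
    # interior collocation point (dimensionless) ...
    fld = synthesize([sol], Nt=Nt)
    ell_nw = lamb_radial(fld)[-2, :]
    ell_max = float(np.abs(ell_nw).max())
    # ... and its pN conversion at the vessel calibre implied by alpha.
    R_alpha = radius_for_alpha(alpha)
    sc = scales_from_config(R=R_alpha)
    ec = ec or ECGeometry()
    force_pN = sc.rho * sc.U0**2 / sc.R * ell_max * A_ref * ec.delta_EC * 1e12
    return swirl, vort, peak_r, ell_max, force_pN


def sweep_mono(
    alpha_grid: Sequence[float] = ALPHA_GRID_DEFAULT,
    beta_grid: Sequence[float] = BETA_GRID_DEFAULT,
    N: int = 150,
) -> SweepResult:
    """Mono-harmonic sweep (h = 1, a = 1) over the alpha x beta grid."""
    alphas = np.asarray(alpha_grid, dtype=float)
    betas = np.asarray(beta_grid, dtype=float)
    if alphas.size == 0 or betas.size == 0:
        raise ValueError("sweep grids must be nonempty")
    grid = cgl_grid(N)
    shape = (alphas.size, betas.size)
    swirl = np.zeros(shape)
    vort = np.zeros(shape)
    loc = np.full(shape, np.nan)
    wf = np.zeros(shape)
    wf_pN = np.zeros(shape)
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            try:
                s, v, p, w, wpn = _mono_cell(grid, a, b)
            except Exception as err:
                raise RuntimeError(f"sweep cell (alpha={a}, beta={b}) failed") from err
            swirl[i, j] = s
            vort[i, j] = v
            loc[i, j] = p if s > 1e-13 else np.nan
            wf[i, j] = w
            wf_pN[i, j] = wpn
    return SweepResult(
        alpha_grid=alphas,
        beta_grid=betas,
        swirl_max=swirl,
        vortz_max=vort,
        peak_loc=loc,
        wall_force=wf,
        wall_force_pN=wf_pN,
    )


def peak_swirl_location(alpha: float, beta: float, N: int = 150) -> float:
    """r/R maximising |Utheta| for mono-harmonic forcing, to 1e-4 resolution."""
    grid = cgl_grid(N)
    ratios = AnisotropyRatios(beta=beta, gamma=beta, delta=1.0)
    sol = solve_mono(grid, alpha, ratios)
    if np.abs(sol.Utheta).max() < 1e-13:
        raise ValueError("swirl profile is identically zero; peak undefined")
    r_best, _ = _refine_peak(grid, sol.Utheta)
    return r_best


# ---------------------------------------------------------------------------
# Grid independence
# ---------------------------------------------------------------------------

N_LIST_DEFAULT = (60, 80, 100, 120, 140, 160)


def _uz_at_phase(record, beta, N, t_star, dtype=np.float64):
    grid = cgl_grid(N, dtype=dtype)
    ratios = AnisotropyRatios(beta=beta, gamma=beta, delta=1.0)
    sols = solve_waveform(grid, record.alpha, ratios, record.waveform)
    pi = np.arccos(dtype(-1.0)) if dtype is not np.float64 else np.pi
    uz = np.zeros(grid.n, dtype=dtype)
    for s in sols:
        ph = np.exp(1j * 2.0 * pi * dtype(s.h) * dtype(t_star))
        uz += np.real(s.Uz * ph)
    return grid, uz


def grid_independence(
    record: WaveformRecord | None = None,
    beta: float = 0.1,
    N_list: Sequence[int] = N_LIST_DEFAULT,
    N_ref: int = 180,
    t_star: float = 0.25,
    extended: bool = True,
) -> pd.DataFrame:
    """Pointwise residual of u_z(r, t*) against the N_ref reference solution.

    The coarse solution is evaluated at the reference nodes by barycentric
    interpolation; residual = max_r |u^(N) - u^(N_ref)| at the peak phase.
    Refinement floors sit below the double-precision rounding of the
    assembled operators, so this protocol solves in 80-bit extended
    precision by default (``extended=False`` reverts to the fast path).
    """
    record = record or get_record("Thoracic Aorta")
    dtype = np.longdouble if extended else np.float64
    grid_ref, uz_ref = _uz_at_phase(record, beta, N_ref, t_star, dtype)
    rows = []
    for N in N_list:
        if N == N_ref:
            rows.append({"N": N, "residual": 0.0})
            continue
        grid_N, uz_N = _uz_at_phase(record, beta, N, t_star, dtype)
        uz_on_ref = grid_N.barycentric_eval(uz_N, grid_ref.nodes)
        rows.append({"N": N, "residual": float(np.abs(uz_on_ref - uz_ref).max())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Force series, spectra, statistics
# ---------------------------------------------------------------------------


def physiological_field(
    record: WaveformRecord, beta: float = 0.1, N: int = 150, Nt: int = 256
) -> FlowField:
    """Multi-harmonic flow field for one artery (beta = gamma, delta = 1)."""
    grid = cgl_grid(N)
    ratios = AnisotropyRatios(beta=beta, gamma=beta, delta=1.0)
    sols = solve_waveform(grid, record.alpha, ratios, record.waveform)
    return synthesize(sols, Nt=Nt)


def physiological_force_series(
    record: WaveformRecord,
    beta: float = 0.1,
    N: int = 150,
    Nt: int = 256,
    ec: ECGeometry | None = None,
    scales: PhysicalScales | None = None,
) -> ECForceSeries:
    """Pillbox force F_EC(t) for one artery at its own calibrated scales."""
    field = physiological_field(record, beta=beta, N=N, Nt=Nt)
    scales = scales or scales_for(record)
    ec = ec or ECGeometry()
    return ec_force(field, scales, ec)


def six_artery_forces(
    beta: float = 0.1, N: int = 150, Nt: int = 256, **kwargs
) -> dict[str, ECForceSeries]:
    """F_EC(t) for every bundled artery (shared beta, per-artery scales)."""
    return {
        rec.name: physiological_force_series(rec, beta=beta, N=N, Nt=Nt, **kwargs)
        for rec in registry()
    }


def force_spectrum(series: ECForceSeries, H_report: int = 6) -> np.ndarray:
    """Per-harmonic power of F_EC(t) over one cycle, h = 0..H_report.

    One-sided amplitudes A_h are converted to mean-square (Parseval
    consistent) power: P_0 = A_0^2, P_h = A_h^2 / 2 for h >= 1 so that
    sum_h P_h ~= mean(F_EC^2).
    """
    t = np.asarray(series.times)
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("force spectrum requires a uniform time grid")
    F = np.asarray(series.F_EC)
    Nt = F.shape[0]
    if H_report >= Nt // 2:
        raise ValueError("H_report must be below the Nyquist harmonic")
    X = np.fft.rfft(F)
    A = np.abs(X[: H_report + 1]) / Nt
    A[1:] *= 2.0
    P = A**2
    P[1:] /= 2.0
    return P


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from chi-square.

    Degenerate input (every value identical across all groups) returns
    (0.0, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*arrays)
    return float(H), float(p)


def truncation_rms(samples: Sequence[float], H: int) -> float:
    """Relative RMS error of the order-H Fourier reconstruction of one period."""
    y = np.asarray(samples, dtype=float)
    Nt = y.shape[0]
    if H >= Nt // 2:
        raise ValueError("H must be below the Nyquist harmonic")
    X = np.fft.rfft(y)
    X[H + 1 :] = 0.0
    recon = np.fft.irfft(X, Nt)
    denom = np.sqrt(np.mean(y**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.mean((y - recon) ** 2)) / denom)
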