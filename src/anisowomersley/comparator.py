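"""Geometric (curvature-driven) transverse-force bound and spectral dominance.

In curved vessel segments the bulk axial motion produces a centrifugal
transverse load that is absent in the straight tube.  It is represented
here only through a conservative order-of-magnitude bound built from the
bulk velocity and the curvature ratio kappa = R / Rcurv:

    bound mode:    f_rc(t) <= rho * u_bulk(t)^2 * (1 + kappa) / R
    scaling mode:  f_rc(r, t) ~ rho * u_bulk(t)^2 * (kappa / R + 1 / r)

Both are integrated over the same endothelial pillbox as the anisotropic
(Lamb-vector) force, giving F_c,EC(t) and F_a,EC(t).  Their harmonic
amplitude spectra are then compared, the geometric side attenuated by the
1/h first-order inertial transfer factor (the bulk cross-stream response
of harmonic h scales like its forcing divided by rho*omega_h).  The
per-harmonic oscillatory-layer thickness of the anisotropic mechanism is
reported as delta_W,h = sqrt(2) / (sqrt(h) alpha) (classical Stokes-layer
prefactor; a reporting convention only, never used inside the solver).

The steady (h = 0) component is excluded from dominance spectra: the 1/h
filter is undefined there and the comparison concerns pulsatile content.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import PhysicalScales
from .forces import ECGeometry, FlowField, ec_force


@dataclass(frozen=True)
class CurvatureSpec:
    """Curvature ratio kappa = R / Rcurv and the secondary-flow scaling tag."""

    kappa: float
    u_s_scale: str = "sqrt_kappa"  # u_s ~ u_z sqrt(kappa)

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("kappa must lie in [0, 1)")

    def radius_of_curvature(self, R: float) -> float:
        """Rcurv = R / kappa (infinite for a straight tube)."""
        return np.inf if self.kappa == 0.0 else R / self.kappa


@dataclass(frozen=True)
class DominanceSpectrum:
    """Per-harmonic geometric (filtered) vs anisotropic force amplitudes."""

    harmonics: np.ndarray = field(repr=False)  # h = 1..H
    F_c_spec: np.ndarray = field(repr=False)  # N, after 1/h filtering
    F_a_spec: np.ndarray = field(repr=False)  # N
    delta_W: np.ndarray = field(repr=False)  # fraction of R
    kappa: float = 0.0


def curvature_bound(
    uz_bulk: np.ndarray,
    spec: CurvatureSpec,
    rho: float,
    R: float,
    mode: str = "bound",
    r: float | None = None,
) -> np.ndarray:
    """Curvature-driven transverse force density f_rc(t) in N/m^3.

    ``bound`` mode is the conservative near-wall upper bound
    rho u^2 (1+kappa)/R; ``scaling`` mode evaluates rho u^2 (kappa/R + 1/r)
    at a caller-specified dimensional radius r.
    """
    u = np.asarray(uz_bulk, dtype=float)
    if mode == "bound":
        return rho * u**2 * (1.0 + spec.kappa) / R
    if mode == "scaling":
        if r is None:
            r = R
        return rho * u**2 * (spec.kappa / R + 1.0 / r)
    raise ValueError(f"unknown mode {mode!r}")


def inertial_filter(amplitudes: np.ndarray, h_start: int = 1) -> np.ndarray:
    """Apply the 1/h bulk-inertia attenuation to harmonic amplitudes.

    ``amplitudes[k]`` is the amplitude of harmonic h = h_start + k; the
    steady component is excluded (h_start must be >= 1).
    """
    if h_start < 1:
        raise ValueError("the 1/h filter is undefined at h = 0; exclude the steady term")
    amps = np.asarray(amplitudes, dtype=float)
    h = np.arange(h_start, h_start + amps.shape[0])
    return amps / h


def quasi_steady_acceleration_ratio(beta: float, kappa: float) -> float:
    """Quasi-steady anisotropic-to-geometric acceleration ratio a_a / a_c.

    Order-of-magnitude estimate at the fundamental frequency: the
    anisotropic transverse acceleration scales with the coupling ratio
    beta, the curvature-driven one with (1 + kappa), giving
    a_a / a_c ~ beta / (1 + kappa).  The formula is a documented
    assumption of this estimate, not a computed solver quantity; e.g.
    beta = 0.1, kappa = 0.3 gives ~0.077.
    """
    if not 0.0 <= kappa < 1.0:
        raise ValueError("kappa must lie in [0, 1)")
    return beta / (1.0 + kappa)


def boundary_layer_thickness(alpha: float, h: int) -> float:
    """Oscillatory-layer thickness delta_W,h = sqrt(2)/(sqrt(h) alpha), as r/R."""
    if h < 1:
        raise ValueError("harmonic index must be >= 1")
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    return float(np.sqrt(2.0) / (np.sqrt(h) * alpha))


def bulk_velocity(field: FlowField, n_quad: int = 128) -> np.ndarray:
    """Instantaneous area-averaged axial velocity 2 * int_0^1 u_z r dr (dimensionless).

    Gauss-Legendre quadrature on the interpolant: exact for the polynomial
    velocity representation whenever 2*n_quad - 1 >= N + 1.
    """
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r_q = 0.5 * (x + 1.0)
    w_q = 0.5 * w
    P = field.grid.interpolation_matrix(r_q)
    u_q = P @ field.uz
    return 2.0 * ((w_q * r_q)[None, :] @ u_q)[0]


def harmonic_amplitudes(series: np.ndarray, H: int) -> np.ndarray:
    """One-sided DFT amplitudes of harmonics h = 1..H over exactly one cycle."""
    Nt = series.shape[0]
    if H >= Nt // 2:
        raise ValueError("H must be below the Nyquist harmonic")
    X = np.fft.rfft(series)
    return 2.0 * np.abs(X[1 : H + 1]) / Nt


def dominance_spectrum(
    field: FlowField,
    spec: CurvatureSpec,
    scales: PhysicalScales,
    ec: ECGeometry,
    H_report: int = 6,
    mode: str = "bound",
) -> DominanceSpectrum:
    """Compare pillbox-integrated geometric vs anisotropic force spectra.

    Both F_c,EC(t) and F_a,EC(t) are built in the time domain, decomposed
    into harmonic amplitudes over one cycle, and the geometric side is
    attenuated by 1/h.
    """
    u_b = bulk_velocity(field) * scales.U0  # m/s
    delta = ec.delta_EC
    if mode == "bound":
        f_rc = curvature_bound(u_b, spec, scales.rho, scales.R, mode="bound")
        F_c_t = ec.A_EC * delta * np.abs(f_rc)
    elif mode == "scaling":
        # radial dependence 1/r integrated exactly across the pillbox
        r_lo = scales.R - delta
        F_c_t = (
            ec.A_EC
            * scales.rho
            * u_b**2
            * (spec.kappa / scales.R * delta + np.log(scales.R / r_lo))
        )
        F_c_t = np.abs(F_c_t)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    F_a_t = ec_force(field, scales, ec).F_EC

    F_c_spec = inertial_filter(harmonic_amplitudes(F_c_t, H_report))
    F_a_spec = harmonic_amplitudes(F_a_t, H_report)
    h = np.arange(1, H_report + 1)
    d_W = np.array([boundary_layer_thickness(field.alpha, int(k)) for k in h])
    return DominanceSpectrum(
        harmonics=h, F_c_spec=F_c_spec, F_a_spec=F_a_spec, delta_W=d_W, kappa=spec.kappa
    )


def dominance_band(
    field: FlowField,
    kappa_low: float,
    kappa_high: float,
    scales: PhysicalScales,
    ec: ECGeometry,
    H_report: int = 6,
    mode: str = "bound",
) -> pd.DataFrame:
    """Dominance spectra at both ends of a curvature band, as a table."""
    lo = dominance_spectrum(field, CurvatureSpec(kappa_low), scales, ec, H_report, mode)
    hi = dominance_spectrum(field, CurvatureSpec(kappa_high), scales, ec, H_report, mode)
    return pd.DataFrame(
        {
            "h": lo.harmonics,
            "F_c_low_N": lo.F_c_spec,
            "F_c_high_N": hi.F_c_spec,
            "F_a_N": lo.F_a_spec,
            "delta_W": lo.delta_W,
        }
    )
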