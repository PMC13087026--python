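"""Chebyshev-Gauss-Lobatto collocation on the unit radius.

The radial domain r* in [0, 1] is discretised at the N+1 CGL nodes
r*_k = (1 + cos(pi k / N)) / 2, stored in ascending order (centerline
first, wall last) so that radial index equals physical ordering and
near-wall slicing is a tail slice.  The first-derivative matrix D is the
standard trigonometric CGL matrix (with the negative-sum trick for the
diagonal, which keeps rounding under control up to N ~ 180) mapped from
[-1, 1] to [0, 1] by the chain-rule factor 2.

Two cylindrical operators are provided:

    L0 f = f'' + f'/r            (axial Laplacian)
    L1 f = f'' + f'/r - f/r^2    (azimuthal Laplacian)

Their centerline rows are singular; they are populated with the regular
symmetric limits (L0 -> 2 f''(0) for even f, L1 -> 1.5 f''(0) for odd f)
but the flow solver always overwrites those rows with boundary conditions,
so the choice is inert in practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


#: Pi to long-double precision (used when grids are built in extended precision).
_PI = {np.dtype(np.float64): np.pi}
_PI[np.dtype(np.longdouble)] = np.longdouble(
    "3.141592653589793238462643383279502884"
)


def _cheb_matrix(N: int, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """CGL differentiation matrix on [-1, 1], x descending.

    Off-diagonal entries use the trigonometric identity
    x_k - x_j = -2 sin((k+j)pi/2N) sin((k-j)pi/2N), the diagonal the
    negative-sum trick, and the lower half the centro-antisymmetry of D
    ("flipping trick").  Together these push the rounding floor of high
    orders (N ~ 180) well below what the naive difference formula allows.
    """
    dtype = np.dtype(dtype)
    pi = _PI[dtype]
    k = np.arange(N + 1)
    x = np.cos(pi * k.astype(dtype) / N)
    c = np.ones(N + 1, dtype)
    c[0] = c[-1] = 2.0
    c *= (-1.0) ** k
    K = np.tile(k, (N + 1, 1)).T
    half = pi / (2 * N)
    denom = 2.0 * np.sin((K + K.T) * half) * np.sin((K - K.T) * half)
    np.fill_diagonal(denom, 1.0)
    D = -np.outer(c, 1.0 / c) / denom
    np.fill_diagonal(D, 0.0)
    # flipping trick: entries with k+j > N (ill-conditioned sin((k+j)pi/2N))
    # are recomputed from the well-conditioned mirror via centro-antisymmetry.
    far = (K + K.T) > N
    D = np.where(far, -D[::-1, ::-1], D)
    np.fill_diagonal(D, 0.0)
    D -= np.diag(D.sum(axis=1))  # negative-sum trick
    return D, x


def _bary_weights(N: int) -> np.ndarray:
    """Barycentric weights of CGL nodes (any consistent ordering, up to sign)."""
    w = (-1.0) ** np.arange(N + 1)
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


@dataclass(frozen=True)
class ChebyshevGrid:
    """CGL nodes on [0, 1] with derivative and cylindrical operator matrices."""

    N: int
    nodes: np.ndarray = field(repr=False)
    D: np.ndarray = field(repr=False)
    D2: np.ndarray = field(repr=False)
    L0: np.ndarray = field(repr=False)
    L1: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Number of nodes, N + 1."""
        return self.N + 1

    def apply_L0(self, f: np.ndarray) -> np.ndarray:
        """f'' + f'/r at the nodes (centerline row uses the even-symmetry limit)."""
        f = np.asarray(f)
        if f.shape[0] != self.n:
            raise ValueError(f"expected {self.n} samples, got {f.shape[0]}")
        return self.L0 @ f

    def apply_L1(self, f: np.ndarray) -> np.ndarray:
        """f'' + f'/r - f/r^2 at the nodes (centerline row: odd-symmetry limit)."""
        f = np.asarray(f)
        if f.shape[0] != self.n:
            raise ValueError(f"expected {self.n} samples, got {f.shape[0]}")
        return self.L1 @ f

    def interpolation_matrix(self, targets) -> np.ndarray:
        """Dense matrix P with (P @ f)[i] = interpolant of f at targets[i].

        Barycentric second-form evaluation of the degree-N interpolant;
        exact at the nodes and for any polynomial of degree <= N.
        """
        t = np.atleast_1d(np.asarray(targets, dtype=float))
        if t.min() < 0.0 or t.max() > 1.0:
            raise ValueError("interpolation targets must lie in [0, 1]")
        w = _bary_weights(self.N)
        diff = t[:, None] - self.nodes[None, :]
        exact_i, exact_j = np.nonzero(diff == 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = w[None, :] / diff
            P = C / C.sum(axis=1, keepdims=True)
        P[exact_i, :] = 0.0
        P[exact_i, exact_j] = 1.0
        return P

    def barycentric_eval(self, f: np.ndarray, targets) -> np.ndarray:
        """Evaluate the interpolant of nodal samples ``f`` at ``targets``."""
        f = np.asarray(f)
        if f.shape[0] != self.n:
            raise ValueError(f"expected {self.n} samples, got {f.shape[0]}")
        return self.interpolation_matrix(targets) @ f

    def to_dict(self) -> dict:
        """JSON-serialisable dump (debugging aid)."""
        return {"N": self.N, "nodes": self.nodes.tolist()}


def cgl_grid(N: int, dtype=np.float64) -> ChebyshevGrid:
    """Build the CGL grid of polynomial order N (N >= 4).

    ``dtype`` may be ``np.longdouble`` for extended-precision grids, used
    by protocols (grid-refinement floors) that must resolve differences
    below the double-precision rounding of the assembled operators.
    """
    if N < 4:
        raise ValueError(f"N must be >= 4, got {N}")
    Dx, x = _cheb_matrix(N, dtype=dtype)
    # Map to r = (1+x)/2 (dr = dx/2) and reorder ascending in r.
    flip = slice(None, None, -1)
    r = ((1.0 + x) / 2.0)[flip]
    r[0] = 0.0
    r[-1] = 1.0
    D = 2.0 * Dx[flip, flip]
    D2 = D @ D
    with np.errstate(divide="ignore"):
        inv_r = 1.0 / r
        inv_r2 = inv_r**2
    inv_r[0] = 0.0
    inv_r2[0] = 0.0
    L0 = D2 + inv_r[:, None] * D
    L1 = D2 + inv_r[:, None] * D - np.diag(inv_r2)
    # Regularised centerline rows (inert in the solver: replaced by BC rows).
    L0[0, :] = 2.0 * D2[0, :]
    L1[0, :] = 1.5 * D2[0, :]
    return ChebyshevGrid(N=N, nodes=r, D=D, D2=D2, L0=L0, L1=L1)


def apply_L0(grid: ChebyshevGrid, f: np.ndarray) -> np.ndarray:
    return grid.apply_L0(f)


def apply_L1(grid: ChebyshevGrid, f: np.ndarray) -> np.ndarray:
    return grid.apply_L1(f)


def barycentric_eval(grid: ChebyshevGrid, f: np.ndarray, targets) -> np.ndarray:
    return grid.barycentric_eval(f, targets)
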