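"""Raw, central and discrete Hahn moments of a 2-D residue grid.

A k-residue window is laid out row-major into an n x n grid with
n = ceil(sqrt(k)) (41-mers give 7 x 7 grids with 8 trailing zeros), and the
grid is summarized by three families of statistical moments up to order 3:

* raw moments      M_ij = sum_{p,q} p^i q^j beta_pq   (1-based coordinates)
* central moments  eta_ij = sum_{p,q} (p - x̄)^i (q - ȳ)^j beta_pq, where
  (x̄, ȳ) = (M10/M00, M01/M00) is the grid centroid
* Hahn moments     H_ij = sum_{p,q} beta_pq h̃_i(p, N) h̃_j(q, N), the
  projection onto the orthonormal discrete Hahn polynomial basis
  (0-based coordinates, N = n)

Each family is reported as the 8-tuple of index pairs
(0,0), (0,1), (1,0), (1,1), (1,2), (2,1), (3,0), (0,3).  None of the
families is scale-invariant — deliberately, since the grid values are
categorical residue codes and ordering information must be preserved.
Central moments are location-invariant about the centroid; the Hahn basis
is orthonormal, so the full moment set is an invertible transform of the
grid ("reversible": the grid can be reconstructed exactly).

The Hahn polynomials are the classical ones, h_n^{(u,v)}(x, N) proportional
to the terminating hypergeometric series
3F2(-n, n+u+v+1, -x; u+1, 1-N; 1), with weight
rho(x) = Gamma(u+x+1) Gamma(v+N-x) / (Gamma(x+1) Gamma(N-x)) and the
classical closed-form square norm.  All Pochhammer/Gamma products are
evaluated in log space so large grids (e.g. 20 x 20 incidence matrices)
do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

#: Index pairs (i, j) of the 8 reported moments, in fixed order.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1), (3, 0), (0, 3),
)

MomentFamily = Literal["raw", "central", "hahn"]


class DegenerateGridError(ValueError):
    """Raised when an all-zero grid has no centroid (M00 = 0)."""


@dataclass(frozen=True)
class MomentSet:
    """The 8 moments of one family on one matrix, in ``MOMENT_ORDERS`` order."""

    family: MomentFamily
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(MOMENT_ORDERS):
            raise ValueError("a MomentSet holds exactly 8 values")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("moments must be finite")

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return self.values[MOMENT_ORDERS.index(ij)]

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)


@dataclass(frozen=True)
class Centroid:
    x: float
    y: float


def reshape_to_grid(codes: Sequence[float] | np.ndarray) -> np.ndarray:
    """Lay a length-k vector row-major into an n x n grid, n = ceil(sqrt(k)).

    Element m (0-based) lands in row floor(m/n), column m mod n (0-based);
    the n^2 - k trailing cells are zero.
    """
    flat = np.asarray(codes, dtype=float).ravel()
    k = flat.size
    if k == 0:
        raise ValueError("cannot grid an empty vector")
    n = math.isqrt(k - 1) + 1  # ceil(sqrt(k)) for k >= 1
    grid = np.zeros(n * n, dtype=float)
    grid[:k] = flat
    return grid.reshape(n, n)


def raw_moments(grid: np.ndarray) -> MomentSet:
    """Raw moments M_ij with grid coordinates p, q running 1..n.

    Starting coordinates at 1 (not 0) keeps first-row/column cells
    contributing to M10/M01.
    """
    grid = np.asarray(grid, dtype=float)
    n = grid.shape[0]
    p = np.arange(1, n + 1, dtype=float)
    vals = tuple(
        float(((p ** i)[:, None] * (p ** j)[None, :] * grid).sum())
        for i, j in MOMENT_ORDERS
    )
    return MomentSet("raw", vals)


def centroid(raw: MomentSet) -> Centroid:
    """Grid centroid (M10/M00, M01/M00)."""
    m00 = raw[(0, 0)]
    if m00 == 0:
        raise DegenerateGridError("all-zero grid has no centroid")
    return Centroid(raw[(1, 0)] / m00, raw[(0, 1)] / m00)


def central_moments(grid: np.ndarray) -> MomentSet:
    """Central moments eta_ij about the centroid; eta00 = M00, eta10 = eta01 = 0."""
    grid = np.asarray(grid, dtype=float)
    c = centroid(raw_moments(grid))
    n = grid.shape[0]
    p = np.arange(1, n + 1, dtype=float)
    dx = p - c.x
    dy = p - c.y
    vals = tuple(
        float(((dx ** i)[:, None] * (dy ** j)[None, :] * grid).sum())
        for i, j in MOMENT_ORDERS
    )
    return MomentSet("central", vals)


# ---------------------------------------------------------------------------
# Discrete Hahn polynomials
# ---------------------------------------------------------------------------

def _log_poch(a: float, k: int) -> tuple[float, float]:
    """Signed log of the Pochhammer rising factorial (a)_k.

    Returns (sign, log|.|); sign 0 encodes an exact zero (a a non-positive
    integer reached within k steps).  Positive a uses log-gamma directly.
    """
    if k == 0:
        return 1.0, 0.0
    if a > 0:
        return 1.0, float(gammaln(a + k) - gammaln(a))
    sign, log = 1.0, 0.0
    for i in range(k):
        t = a + i
        if t == 0:
            return 0.0, -math.inf
        if t < 0:
            sign = -sign
        log += math.log(abs(t))
    return sign, log


def hahn_polynomial(n: int, r: int, N: int, u: float = 0.0,
                    v: float = 0.0) -> float:
    """Unnormalized discrete Hahn polynomial h_n^{(u,v)}(r, N).

    Classical Hahn series with the conventional prefactor
    (N+v-1)_n (N-1)_n; terms are accumulated from signed log-space
    Pochhammer products for stability at large N.
    """
    if not 0 <= n <= N - 1:
        raise ValueError(f"order {n} outside 0..{N - 1}")
    if not 0 <= r <= N - 1:
        raise ValueError(f"argument {r} outside 0..{N - 1}")
    ps, pl = _log_poch(N + v - 1, n)
    qs, ql = _log_poch(N - 1, n)
    pref_sign, pref_log = ps * qs, pl + ql

    sgns, logs = [], []
    for k in range(n + 1):
        s1, l1 = _log_poch(-n, k)
        s2, l2 = _log_poch(n + u + v + 1, k)
        s3, l3 = _log_poch(-r, k)
        d1, dl1 = _log_poch(u + 1, k)
        d2, dl2 = _log_poch(1 - N, k)
        if 0.0 in (s1, s2, s3):
            continue
        if 0.0 in (d1, d2):  # cannot happen for k <= n <= N-1
            raise ZeroDivisionError("degenerate Hahn denominator")
        sgns.append(s1 * s2 * s3 * d1 * d2)
        logs.append(l1 + l2 + l3 - dl1 - dl2 - float(gammaln(k + 1)))
    if not logs:
        return 0.0
    m = max(logs)
    series = sum(s * math.exp(log - m) for s, log in zip(sgns, logs))
    return pref_sign * series * math.exp(m + pref_log)


def hahn_weight(r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Hahn orthogonality weight rho(r) on r = 0..N-1."""
    return math.exp(
        gammaln(u + r + 1) + gammaln(v + N - r)
        - gammaln(r + 1) - gammaln(N - r))


def hahn_norm_sq(n: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Square norm d_n^2 = sum_r rho(r) h_n(r, N)^2, in closed form.

    Classical Hahn square norm scaled by the prefactor of
    :func:`hahn_polynomial` and by the Gamma(u+1)Gamma(v+1) constant that
    relates :func:`hahn_weight` to the binomial-product weight.
    """
    M = N - 1
    log = (
        gammaln(n + u + v + 1 + M + 1) - gammaln(n + u + v + 1)  # (n+u+v+1)_{M+1}
        + gammaln(v + 1 + n) - gammaln(v + 1)                    # (v+1)_n
        + gammaln(n + 1) + gammaln(M - n + 1)
        - math.log(2 * n + u + v + 1)
        - (gammaln(u + 1 + n) - gammaln(u + 1))                  # (u+1)_n
        - 2 * gammaln(M + 1)
        + gammaln(u + 1) + gammaln(v + 1)
    )
    _, pl = _log_poch(N + v - 1, n)
    _, ql = _log_poch(N - 1, n)
    return math.exp(log + 2 * (pl + ql))


@lru_cache(maxsize=32)
def hahn_basis(N: int, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Orthonormal Hahn basis matrix B with B[n, r] = h̃_n(r, N).

    h̃_n(r) = h_n(r) sqrt(rho(r) / d_n^2); rows are orthonormal:
    B @ B.T = I.  Cached per (N, u, v).
    """
    B = np.empty((N, N), dtype=float)
    for n in range(N):
        d2 = hahn_norm_sq(n, N, u, v)
        for r in range(N):
            B[n, r] = (hahn_polynomial(n, r, N, u, v)
                       * math.sqrt(hahn_weight(r, N, u, v) / d2))
    B.setflags(write=False)
    return B


def hahn_transform(grid: np.ndarray, u: float = 0.0,
                   v: float = 0.0) -> np.ndarray:
    """All N^2 normalized Hahn moments H of a square grid: H = B beta B^T."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("Hahn moments require a square grid")
    B = hahn_basis(grid.shape[0], u, v)
    return B @ grid @ B.T


def inverse_hahn_transform(H: np.ndarray, u: float = 0.0,
                           v: float = 0.0) -> np.ndarray:
    """Reconstruct the grid from its full Hahn moment matrix (orthonormality)."""
    H = np.asarray(H, dtype=float)
    B = hahn_basis(H.shape[0], u, v)
    return B.T @ H @ B


def hahn_moments(grid: np.ndarray, u: float = 0.0, v: float = 0.0) -> MomentSet:
    """The 8 reported normalized Hahn moments of a square grid."""
    H = hahn_transform(grid, u, v)
    return MomentSet("hahn", tuple(float(H[i, j]) for i, j in MOMENT_ORDERS))
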