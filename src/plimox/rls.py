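"""Closed-form regularized least squares and its fast window reduction.

The physiological prior is that oxygen tension varies negligibly within a
3x3 pixel neighbourhood (~15x15 um^2).  Encoding the neighbourhood sample
mean through a sparse weighting matrix K (self weight l, edge-adjacent p,
diagonal-adjacent q, with l + 4p + 4q = 1) turns the per-pixel regularized
cost into a global quadratic whose exact minimizer is

    a1_RLS = L^{-1} a1_LS,   b1_RLS = L^{-1} b1_LS,
    L = I + beta * (I + K^T K - K - K^T) = I + beta * (I - K)^T (I - K),

i.e. a single sparse solve applied to the conventional LS maps.  Because K
is a banded Toeplitz matrix and L is Toeplitz away from its first and last
2R+2 rows, L^{-1} is near-Toeplitz: its rows are shifts of one another, and
the significant entries of any interior row change negligibly with the map
size.  The fast method exploits this by computing L_s^{-1} once on a small
R_s x R_s map (dimension R_s^2), taking the middle row, reshaping it
column-major into an R_s x R_s weighted-averaging window, and applying that
window to the LS maps by 2-D cross-correlation — reducing the global
regularized solve to a convolution whose cost is independent of beta and
linear in the number of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import correlate

from .core import MapGeometry, ParameterMaps

__all__ = [
    "RegularizerSpec",
    "NeighborMatrix",
    "SmoothingWindow",
    "build_neighbor_matrix",
    "build_L",
    "rls_direct",
    "extract_window",
    "rls_fast",
]

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class RegularizerSpec:
    """Neighbourhood weights, regularization strength, and window size.

    Parameters
    ----------
    l, p, q
        Weight of a pixel on itself, on its four edge-adjacent neighbours,
        and on its four diagonal neighbours.  Must satisfy l + 4p + 4q = 1
        so that K averages (interior rows of K sum to one).
    beta
        Regularization strength; beta = 0 disables smoothing entirely.
    window_size
        Odd side length R_s of the small map used to extract the averaging
        window (odd so the middle row is centrally symmetric).
    """

    l: float = 0.5
    p: float = 0.1
    q: float = 0.025
    beta: float = 5.0
    window_size: int = 13

    def __post_init__(self) -> None:
        if min(self.l, self.p, self.q) < 0:
            raise ValueError("neighbourhood weights must be non-negative")
        s = self.l + 4 * self.p + 4 * self.q
        if abs(s - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(
                f"weights must satisfy l + 4p + 4q = 1; got {s!r}"
            )
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd positive integer")


@dataclass
class NeighborMatrix:
    """Sparse symmetric M x M neighbourhood weighting matrix K."""

    entries: sp.spmatrix
    geometry: MapGeometry
    spec: RegularizerSpec


@dataclass
class SmoothingWindow:
    """R_s x R_s weighted-averaging window extracted from L_s^{-1}.

    ``raw_sum`` records the pre-normalization sum of the middle row of
    L_s^{-1} (close to, but not exactly, 1 because of the boundary rows of
    K_s); ``weights`` is renormalized to sum exactly 1 so constants pass
    through unchanged.
    """

    weights: np.ndarray
    beta: float
    normalized: bool
    raw_sum: float


def build_neighbor_matrix(
    geometry: MapGeometry, spec: RegularizerSpec, wrap: bool = True
) -> NeighborMatrix:
    """Build the banded weighting matrix K for a column-major R x C map.

    K(j,k) = l if j = k; p if |j-k| in {1, R}; q if |j-k| in {R-1, R+1};
    0 otherwise.  With column-major vectorization these offsets address the
    3x3 neighbourhood of each pixel.

    By default the matrix is the literal Toeplitz band, which links the last
    pixel of one column to the first pixel of the next (the boundary-row
    artifact the 2R+2-row error analysis of the fast method presumes).
    ``wrap=False`` instead zeroes those cross-column couplings, giving the
    graph-exact 8-neighbour matrix; interior rows are identical either way.
    """
    R = geometry.n_rows
    M = geometry.n_pixels
    if M < 2 * (R + 1) + 1:
        raise ValueError("map too small for the 3x3 neighbourhood band")

    def band(offset: int, value: float) -> np.ndarray:
        d = np.full(M - abs(offset), value)
        if not wrap:
            # zero couplings that cross a column boundary under the
            # column-major convention (r0 = within-column row index)
            r0 = np.arange(M - abs(offset)) % R
            if abs(offset) == 1:
                d[r0 == R - 1] = 0.0
            elif abs(offset) == R - 1:
                d[r0 == 0] = 0.0
            elif abs(offset) == R + 1:
                d[r0 == R - 1] = 0.0
        return d

    offsets = [0, 1, -1, R, -R, R - 1, -(R - 1), R + 1, -(R + 1)]
    values = [spec.l] + [spec.p] * 4 + [spec.q] * 4
    diags = [band(o, v) for o, v in zip(offsets, values)]
    K = sp.diags(diags, offsets, shape=(M, M), format="csr")
    return NeighborMatrix(entries=K, geometry=geometry, spec=spec)


def build_L(K: NeighborMatrix, beta: float) -> sp.csc_matrix:
    """L = I + beta * (I - K)^T (I - K); symmetric with eigenvalues >= 1.

    The quadratic-form representation makes L invertible for every
    beta >= 0 regardless of whether K itself is positive definite.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    M = K.entries.shape[0]
    I = sp.identity(M, format="csr")
    D = (I - K.entries).tocsr()
    L = (I + beta * (D.T @ D)).tocsc()
    return L


def rls_direct(
    ls_params: ParameterMaps, K: NeighborMatrix, beta: float
) -> ParameterMaps:
    """Exact closed-form RLS estimate: solve L a1 = a1_LS and L b1 = b1_LS.

    Uses one sparse LU factorization shared by both solves; L^{-1} is never
    formed.  a0 passes through unregularized (pO2 depends only on the ratio
    b1/a1, and the closed form is derived for a1, b1 only).
    """
    geom = ls_params.geometry
    if geom != K.geometry:
        raise ValueError(
            f"geometry mismatch: maps are {geom.shape}, K was built for "
            f"{K.geometry.shape}"
        )
    if beta == 0:
        return ls_params.copy()
    L = build_L(K, beta)
    solve = spla.factorized(L)
    a1 = geom.unravel(solve(geom.ravel(ls_params.a1)))
    b1 = geom.unravel(solve(geom.ravel(ls_params.b1)))
    return ParameterMaps(a0=ls_params.a0.copy(), a1=a1, b1=b1)


def extract_window(spec: RegularizerSpec, wrap: bool = True) -> SmoothingWindow:
    """Derive the R_s x R_s averaging window from the middle row of L_s^{-1}.

    Builds K_s and L_s for a small R_s x R_s map (dimension R_s^2), solves
    L_s w = e_mid for the middle unit vector (index (R_s^2+1)/2, 1-based),
    reshapes w column-major to R_s x R_s, and renormalizes to sum exactly 1.
    Since L_s is symmetric this w is the middle row of L_s^{-1}.
    """
    Rs = spec.window_size
    if Rs % 2 == 0:
        raise ValueError("window_size must be odd")
    if spec.beta == 0:
        w = np.zeros((Rs, Rs))
        w[Rs // 2, Rs // 2] = 1.0
        return SmoothingWindow(weights=w, beta=0.0, normalized=True, raw_sum=1.0)
    geom = MapGeometry(Rs, Rs)
    K = build_neighbor_matrix(geom, spec, wrap=wrap)
    L = build_L(K, spec.beta)
    e = np.zeros(geom.n_pixels)
    e[(geom.n_pixels - 1) // 2] = 1.0
    w = spla.spsolve(L, e)
    raw_sum = float(w.sum())
    W = geom.unravel(w) / raw_sum
    return SmoothingWindow(
        weights=W, beta=spec.beta, normalized=True, raw_sum=raw_sum
    )


def rls_fast(
    ls_params: ParameterMaps,
    window: SmoothingWindow,
    border_mode: str = "reflect",
) -> ParameterMaps:
    """Approximate RLS by weighted averaging of the LS maps.

    2-D cross-correlation of the a1 and b1 LS maps with the extracted
    window, with symmetric (mirror) border padding by default; a0 passes
    through.  On interior pixels (margin >= (R_s-1)/2 + 2 from every edge)
    the result agrees with :func:`rls_direct` to high accuracy; the paper's
    boundary-row error analysis concedes degradation near edges.
    """
    W = window.weights
    R, C = ls_params.a0.shape
    if W.shape[0] > R or W.shape[1] > C:
        raise ValueError(
            f"window {W.shape} larger than map ({R}, {C}) in some dimension"
        )
    a1 = correlate(ls_params.a1, W, mode=border_mode)
    b1 = correlate(ls_params.b1, W, mode=border_mode)
    return ParameterMaps(a0=ls_params.a0.copy(), a1=a1, b1=b1)
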