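"""Conventional pixelwise least-squares fit of the phase sinusoid.

The design matrix A (rows (1, cos theta_s, sin theta_s)) is shared by every
pixel, so the LS fit of all M pixels is a single 3 x S matrix (the
pseudo-inverse Q) applied to the S x M data matrix.  For phases equally
spaced over a full cycle A.T @ A = diag(S, S/2, S/2), and the rows of Q
reduce to Q(1,:) = (1/S) 1^T, Q(2,:) = (2/S) cos(theta), Q(3,:) =
(2/S) sin(theta) — the identities the closed-form regularized estimates
build on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import (
    AcquisitionModel,
    ParameterMaps,
    PhaseImageStack,
    build_design_matrix,
)

__all__ = ["LSFit", "pseudo_inverse", "ls_estimate"]


@dataclass
class LSFit:
    """LS parameter maps plus the pseudo-inverse and per-pixel residual norm."""

    params: ParameterMaps
    pseudo_inverse: np.ndarray  # 3 x S
    residual_norm: np.ndarray  # R x C


def pseudo_inverse(acquisition: AcquisitionModel) -> np.ndarray:
    """3 x S matrix Q with Q @ A = I, via Cholesky on the normal equations.

    A.T @ A is symmetric positive definite whenever the design has full
    column rank (guaranteed by build_design_matrix), so the Cholesky solve is
    numerically safe and never forms an explicit inverse.
    """
    A = build_design_matrix(acquisition)
    c, low = scipy.linalg.cho_factor(A.T @ A)
    return scipy.linalg.cho_solve((c, low), A.T)


def ls_estimate(stack: PhaseImageStack) -> LSFit:
    """Pixelwise LS estimate (a0, a1, b1) = Q @ y for every pixel.

    Computed as one matrix product over the whole stack; the estimator is
    linear in the data.
    """
    acq = stack.acquisition
    Q = pseudo_inverse(acq)
    Y = stack.intensities  # S x R x C
    X = np.einsum("ks,sij->kij", Q, Y)
    params = ParameterMaps(a0=X[0], a1=X[1], b1=X[2])
    A = build_design_matrix(acq)
    resid = Y - np.einsum("sk,kij->sij", A, X)
    residual_norm = np.sqrt(np.sum(resid**2, axis=0))
    return LSFit(params=params, pseudo_inverse=Q, residual_norm=residual_norm)
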