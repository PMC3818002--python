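"""Iterative reference solver for the global regularized cost.

Kept as the oracle and runtime-comparison subject: the global cost

    C(X) = ||Y - A X||_F^2
         + (S*beta/2) * ( ||(I-K) a0||^2 + ||(I-K) a1||^2 + ||(I-K) b1||^2 )

is a strictly convex quadratic in (a1, b1), so any convergent descent
reaches the same minimizer as the closed-form solve in :mod:`plimox.rls`.
(The regularization coefficient gamma of the per-pixel formulation relates
to beta as gamma = S*beta/2, forced by matching the gradient of the expanded
cost to the closed-form normal equations.)

Because the cost is quadratic, a literal Newton-Raphson step is one exact
linear solve — i.e. the closed-form solution itself.  The iterative solver
therefore implements fixed-step gradient descent, initialized at the LS
estimate, which preserves the structure of the runtime comparison between
iterative and window-based estimation: its iteration count grows with beta
(the step size shrinks as the Hessian S*L stiffens) while the fast method's
cost is beta-independent.

a0 is held at its LS value during iteration: pO2 depends only on (a1, b1)
and the closed form is derived for those two maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import ParameterMaps, PhaseImageStack, build_design_matrix
from .ls import ls_estimate
from .rls import NeighborMatrix

__all__ = [
    "IterativeConfig",
    "IterativeResult",
    "global_cost",
    "cost_gradient",
    "rls_iterate",
    "auto_step_size",
    "paper_step_size",
]

_EQUI_TOL = 1e-10


def _check_equispaced(stack: PhaseImageStack) -> np.ndarray:
    """Return A, rejecting phase sets without the diagonal A^T A structure."""
    A = build_design_matrix(stack.acquisition)
    S = stack.acquisition.n_obs
    G = A.T @ A
    target = np.diag([S, S / 2, S / 2])
    if not np.allclose(G, target, atol=1e-8 * S):
        raise ValueError(
            "phases are not equally spaced over a full cycle (A^T A is not "
            "diag(S, S/2, S/2)); use rls_direct on the generalized problem"
        )
    return A


@dataclass(frozen=True)
class IterativeConfig:
    """Gradient-descent configuration.

    step_size
        "auto" (default): safe step 2 / (S*(1 + beta*lambda_max((I-K)^2)) + eps),
        strictly below the descent-stability bound 2/lambda_max(Hessian).
        "paper": delta = 1/(S*(1+beta)) (the printed step-size rule under the
        weight constraint l+4p+4q=1, rescaled by 1/S to act on the summed
        gradient); checked against the stability bound at construction time
        of the iteration, not of this config.
        A fixed positive float is also accepted and likewise checked.
    """

    step_size: Union[str, float] = "auto"
    max_iters: int = 2000
    grad_tol: float = 1e-10
    record_trace: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.step_size, str):
            if self.step_size not in ("auto", "paper"):
                raise ValueError("step_size must be 'auto', 'paper', or a float")
        elif self.step_size <= 0:
            raise ValueError("fixed step_size must be positive")
        if self.max_iters < 1 or self.grad_tol <= 0:
            raise ValueError("max_iters must be >= 1 and grad_tol > 0")


@dataclass
class IterativeResult:
    params: ParameterMaps
    cost_trace: np.ndarray
    grad_norms: np.ndarray
    n_iters: int
    converged: bool
    step_size: float = 0.0


def _smoothness_operator(K: NeighborMatrix) -> sp.csr_matrix:
    I = sp.identity(K.entries.shape[0], format="csr")
    D = (I - K.entries).tocsr()
    return (D.T @ D).tocsr()


def _lambda_max_DtD(K: NeighborMatrix) -> float:
    """Largest eigenvalue of (I-K)^T(I-K), dense for small maps else Lanczos."""
    DtD = _smoothness_operator(K)
    M = DtD.shape[0]
    if M <= 400:
        return float(np.linalg.eigvalsh(DtD.toarray()).max())
    val = spla.eigsh(DtD, k=1, which="LA", return_eigenvectors=False)
    return float(val[0])


def auto_step_size(S: int, beta: float, K: NeighborMatrix) -> float:
    """Safe fixed step: 2 / (S*(1 + beta*lambda_max((I-K)^2)) + eps), eps = S.

    The Hessian of the cost in a1 (or b1) is S*(I + beta*(I-K)^T(I-K)), with
    eigenvalues in [S, S*(1 + beta*lambda_max)].  Taking the margin eps equal
    to the smallest Hessian eigenvalue S makes this the optimal fixed step
    2/(lambda_min + lambda_max): monotone descent with the best worst-case
    contraction (kappa-1)/(kappa+1), instead of near-stagnation of the top
    mode at the bare stability bound.
    """
    lam = _lambda_max_DtD(K)
    return 2.0 / (S * (1.0 + beta * lam) + S)


def paper_step_size(S: int, beta: float, spec_weight_sum: float = 1.0) -> float:
    """delta = [2 + 2*beta*(l+4p+4q)]^{-1} * 2 / S = 1/(S*(1+beta)) under the
    weight constraint; rescaled by 1/S because the summed gradient carries a
    factor S."""
    return 1.0 / (S * (1.0 + beta * spec_weight_sum))


def global_cost(
    params: ParameterMaps,
    stack: PhaseImageStack,
    K: NeighborMatrix,
    beta: float,
    cross_check: bool = True,
) -> float:
    """Global regularized cost ||Y-AX||_F^2 + (S*beta/2)*sum ||(I-K)m||^2.

    Computed directly in Frobenius form; when the design is equally spaced
    and ``cross_check`` is on, the trace-expanded form (data energy plus
    diagonal quadratic terms) is evaluated too and the two are required to
    agree to 1e-8 relative — an internal consistency check of the expansion
    the closed-form estimates descend from.
    """
    geom = params.geometry
    if geom != stack.geometry or geom != K.geometry:
        raise ValueError("params, stack and K geometries must match")
    A = build_design_matrix(stack.acquisition)
    S = stack.acquisition.n_obs
    # column-major pixel order, consistent with K's band structure
    Y = stack.intensities.transpose(0, 2, 1).reshape(S, geom.n_pixels)
    X = np.stack(
        [geom.ravel(params.a0), geom.ravel(params.a1), geom.ravel(params.b1)]
    )
    I = sp.identity(K.entries.shape[0], format="csr")
    D = (I - K.entries).tocsr()
    resid = Y - A @ X
    reg = sum(float(np.dot(D @ X[k], D @ X[k])) for k in range(3))
    cost = float(np.sum(resid**2)) + (S * beta / 2.0) * reg

    if cross_check:
        G = A.T @ A
        if np.allclose(G, np.diag([S, S / 2, S / 2]), atol=1e-8 * S):
            YtA = Y.T @ A  # M x 3
            expanded = (
                float(np.sum(Y**2))
                + float(X[0] @ (S * X[0] - 2 * YtA[:, 0]))
                + float(X[1] @ ((S / 2) * X[1] - 2 * YtA[:, 1]))
                + float(X[2] @ ((S / 2) * X[2] - 2 * YtA[:, 2]))
                + (S * beta / 2.0) * reg
            )
            scale = max(abs(cost), abs(expanded), 1e-30)
            if abs(cost - expanded) > 1e-8 * scale:
                raise AssertionError(
                    "Frobenius and expanded cost disagree beyond 1e-8 relative"
                )
    return cost


def cost_gradient(
    params: ParameterMaps,
    stack: PhaseImageStack,
    K: NeighborMatrix,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the global cost w.r.t. the a1 and b1 maps.

    grad_a1 = S*a1 - 2*(Y^T A)(:,2) + S*beta*(I - 2K + K^2) a1 and the b1
    analogue; requires equally spaced phases (diagonal A^T A).  Since K is
    symmetric, (I - 2K + K^2) = (I-K)^T (I-K).
    """
    geom = params.geometry
    if geom != stack.geometry or geom != K.geometry:
        raise ValueError("params, stack and K geometries must match")
    A = _check_equispaced(stack)
    S = stack.acquisition.n_obs
    Y = stack.intensities.transpose(0, 2, 1).reshape(S, geom.n_pixels)
    YtA = Y.T @ A
    DtD = _smoothness_operator(K)
    a1 = geom.ravel(params.a1)
    b1 = geom.ravel(params.b1)
    ga = S * a1 - 2 * YtA[:, 1] + S * beta * (DtD @ a1)
    gb = S * b1 - 2 * YtA[:, 2] + S * beta * (DtD @ b1)
    return geom.unravel(ga), geom.unravel(gb)


def rls_iterate(
    stack: PhaseImageStack,
    K: NeighborMatrix,
    beta: float,
    config: Optional[IterativeConfig] = None,
) -> IterativeResult:
    """Fixed-step gradient descent on the global cost, initialized at LS.

    Descends until the joint gradient norm over (a1, b1) falls below
    ``grad_tol`` times the initial gradient norm (or max_iters).  The cost
    trace is non-increasing for any step inside the stability region; on
    convergence the estimate matches :func:`plimox.rls.rls_direct` — the
    unique minimizer of the strictly convex quadratic.
    """
    config = config or IterativeConfig()
    A = _check_equispaced(stack)
    S = stack.acquisition.n_obs
    geom = stack.geometry
    if geom != K.geometry:
        raise ValueError("stack and K geometries must match")

    fit = ls_estimate(stack)
    params = fit.params.copy()
    if beta == 0:
        cost0 = global_cost(params, stack, K, 0.0, cross_check=False)
        return IterativeResult(
            params=params,
            cost_trace=np.array([cost0]),
            grad_norms=np.array([0.0]),
            n_iters=0,
            converged=True,
            step_size=0.0,
        )

    if config.step_size == "auto":
        delta = auto_step_size(S, beta, K)
    elif config.step_size == "paper":
        delta = paper_step_size(S, beta)
    else:
        delta = float(config.step_size)
    # descent-stability check against the Hessian S*(I + beta*(I-K)^T(I-K))
    lam_hess = S * (1.0 + beta * _lambda_max_DtD(K))
    if delta >= 2.0 / lam_hess:
        raise ValueError(
            f"step size {delta:.3e} violates the stability bound "
            f"2/lambda_max(Hessian) = {2.0 / lam_hess:.3e}"
        )

    Y = stack.intensities.transpose(0, 2, 1).reshape(S, geom.n_pixels)
    YtA = Y.T @ A
    DtD = _smoothness_operator(K)
    a1 = geom.ravel(params.a1).copy()
    b1 = geom.ravel(params.b1).copy()

    def grad(v: np.ndarray, col: int) -> np.ndarray:
        return S * v - 2 * YtA[:, col] + S * beta * (DtD @ v)

    costs, gnorms = [], []
    ga, gb = grad(a1, 1), grad(b1, 2)
    g0 = float(np.sqrt(np.dot(ga, ga) + np.dot(gb, gb)))
    tol = config.grad_tol * max(g0, 1e-300)
    converged = g0 <= tol
    n = 0
    while n < config.max_iters and not converged:
        a1 -= delta * ga
        b1 -= delta * gb
        n += 1
        ga, gb = grad(a1, 1), grad(b1, 2)
        gn = float(np.sqrt(np.dot(ga, ga) + np.dot(gb, gb)))
        gnorms.append(gn)
        if config.record_trace:
            p = ParameterMaps(params.a0, geom.unravel(a1), geom.unravel(b1))
            costs.append(global_cost(p, stack, K, beta, cross_check=False))
        if gn <= tol:
            converged = True
    if not converged:
        warnings.warn(
            f"gradient descent did not reach grad_tol within "
            f"{config.max_iters} iterations (grad norm "
            f"{gnorms[-1] if gnorms else g0:.3e}); returning best iterate",
            RuntimeWarning,
        )
    out = ParameterMaps(
        a0=params.a0.copy(), a1=geom.unravel(a1), b1=geom.unravel(b1)
    )
    return IterativeResult(
        params=out,
        cost_trace=np.asarray(costs),
        grad_norms=np.asarray(gnorms),
        n_iters=n,
        converged=converged,
        step_size=delta,
    )
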