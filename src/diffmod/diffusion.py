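"""Network propagation (random walk with restart) steady states.

The propagation recurrence

    x_{t+1} = alpha * W @ x_t + (1 - alpha) * x0

with ``W`` the symmetrically normalised adjacency and ``0 < alpha < 1``
is a contraction (spectral radius of ``alpha*W`` < 1), so it converges
to the unique steady state ``x*`` solving the open-system Laplacian
balance ``(I - alpha*W) x* = (1 - alpha) x0``.  Both the fixed-point
iteration and the direct linear solve are provided; they agree to
numerical tolerance and the residual of the linear system is the
steady-state verification contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DiffusionResult",
    "propagate_iterative",
    "propagate_closed_form",
    "check_steady_state",
]


@dataclass(frozen=True)
class DiffusionResult:
    """Steady state of a network propagation run.

    Attributes
    ----------
    x_star:
        The steady-state vector.
    iterations:
        Number of iterations performed (0 for the closed-form solve).
    residual:
        Max-norm of the final update (iterative) or of the linear-system
        residual (closed form).
    alpha:
        Restart/smoothing parameter used.
    """

    x_star: np.ndarray
    iterations: int
    residual: float
    alpha: float


def _check_inputs(W, x0: np.ndarray, alpha: float) -> np.ndarray:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    x0 = np.asarray(x0, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    if W.shape[0] != W.shape[1] or W.shape[0] != x0.size:
        raise ValueError(f"dimension mismatch: W {W.shape}, x0 {x0.shape}")
    return x0


def propagate_iterative(
    W,
    x0: np.ndarray,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> DiffusionResult:
    """Iterate ``x <- alpha*W x + (1-alpha)*x0`` until the max-norm update
    falls below ``tol``.

    The iterate starts at ``x0`` itself; the fixed point is unique so the
    starting point only affects the iteration count.

    Raises
    ------
    ValueError
        For ``alpha`` outside (0, 1) or mismatched dimensions.
    RuntimeError
        If ``max_iter`` is reached before convergence (the message
        reports the last residual).
    """
    x0 = _check_inputs(W, x0, alpha)
    W = sp.csr_matrix(W)
    b = (1.0 - alpha) * x0
    x = x0.copy()
    for t in range(1, max_iter + 1):
        x_next = alpha * (W @ x) + b
        residual = float(np.max(np.abs(x_next - x))) if x.size else 0.0
        x = x_next
        if residual < tol:
            return DiffusionResult(x, t, residual, alpha)
    raise RuntimeError(
        f"propagation did not converge in {max_iter} iterations (residual {residual:.3e} >= tol {tol:.1e})"
    )


def propagate_closed_form(W, x0: np.ndarray, alpha: float = 0.7) -> DiffusionResult:
    """Solve ``(I - alpha*W) x* = (1-alpha) x0`` directly.

    For ``0 < alpha < 1`` and spectral radius of W at most 1 the system
    is non-singular; a singular factorisation is still guarded against.
    """
    x0 = _check_inputs(W, x0, alpha)
    n = x0.size
    if n == 0:
        return DiffusionResult(x0.copy(), 0, 0.0, alpha)
    A = (sp.identity(n, format="csc") - alpha * sp.csc_matrix(W)).tocsc()
    try:
        x_star = spla.spsolve(A, (1.0 - alpha) * x0)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"singular propagation system: {exc}") from exc
    x_star = np.atleast_1d(np.asarray(x_star, dtype=np.float64))
    if not np.all(np.isfinite(x_star)):
        raise np.linalg.LinAlgError("singular propagation system")
    residual = check_steady_state(W, x0, alpha, x_star)
    return DiffusionResult(x_star, 0, residual, alpha)


def steady_state_solver(W, alpha: float = 0.7):
    """Return a function ``x0 -> x*`` with the LU factorisation of
    ``I - alpha*W`` computed once.

    Useful when many vectors are diffused on the same network, e.g. the
    permutation null of the Sp index.
    """
    n = W.shape[0]
    A = (sp.identity(n, format="csc") - alpha * sp.csc_matrix(W)).tocsc()
    lu = spla.splu(A)
    scale = 1.0 - alpha

    def solve(x0: np.ndarray) -> np.ndarray:
        return lu.solve(scale * np.asarray(x0, dtype=np.float64))

    return solve


def check_steady_state(W, x0: np.ndarray, alpha: float, x_star: np.ndarray) -> float:
    """Max-norm residual of the steady-state balance
    ``(I - alpha*W) x* - (1-alpha) x0``."""
    x0 = np.asarray(x0, dtype=np.float64).ravel()
    x_star = np.asarray(x_star, dtype=np.float64).ravel()
    if x0.size == 0:
        return 0.0
    r = x_star - alpha * (sp.csr_matrix(W) @ x_star) - (1.0 - alpha) * x0
    return float(np.max(np.abs(r)))
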