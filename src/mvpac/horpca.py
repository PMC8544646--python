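"""Higher-order robust PCA (Singleton model) via ADAL.

Decomposes a tensor ``A`` into ``L + S`` by solving

    min_{L,S}  sum_i ||L_(i)||_*  +  lambda ||vec(S)||_1   s.t.  L + S = A

with one auxiliary low-rank tensor per mode, singular-value thresholding on
each unfolding, elementwise soft thresholding for the sparse part, and dual
ascent (alternating-direction augmented Lagrangian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HoRPCADecomposition",
    "mode_unfold",
    "mode_fold",
    "svt",
    "soft_threshold",
    "default_lambda",
    "horpca_singleton",
]


@dataclass
class HoRPCADecomposition:
    """Result of a HoRPCA run."""

    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    primal_residual: float
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    fixed_point_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    # aliases matching the usual L/S notation
    @property
    def L(self) -> np.ndarray:
        return self.low_rank

    @property
    def S(self) -> np.ndarray:
        return self.sparse


def mode_unfold(tensor: np.ndarray, n: int) -> np.ndarray:
    """Mode-``n`` unfolding: mode-``n`` fibers become columns.

    Uses the row-major fiber ordering (mode ``n`` moved first, remaining modes
    kept in their original order); :func:`mode_fold` is its exact inverse.
    """
    tensor = np.asarray(tensor)
    if not 0 <= n < tensor.ndim:
        raise ValueError(f"mode {n} out of range for order-{tensor.ndim} tensor")
    return np.moveaxis(tensor, n, 0).reshape(tensor.shape[n], -1)


def mode_fold(matrix: np.ndarray, n: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`mode_unfold` for a tensor of the given shape."""
    shape = tuple(shape)
    if not 0 <= n < len(shape):
        raise ValueError(f"mode {n} out of range for shape {shape}")
    moved = (shape[n],) + shape[:n] + shape[n + 1 :]
    return np.moveaxis(np.asarray(matrix).reshape(moved), 0, n)


def svt(matrix: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding (proximal operator of the nuclear norm)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite input")
    if tau == 0:
        return matrix.copy()
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def soft_threshold(tensor: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft thresholding ``sign(x) max(|x| - tau, 0)``."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    tensor = np.asarray(tensor, dtype=float)
    return np.sign(tensor) * np.maximum(np.abs(tensor) - tau, 0.0)


def default_lambda(shape: tuple[int, ...], literal: bool = False) -> float:
    """Sparsity weight from the tensor shape: ``1/sqrt(I_max)`` by default.

    ``literal=True`` selects the alternative ``1/I_max`` reading.
    """
    imax = max(shape)
    return 1.0 / imax if literal else 1.0 / np.sqrt(imax)


def _objective(tensors: list[np.ndarray], S: np.ndarray, lam: float) -> float:
    nuc = sum(
        np.linalg.svd(mode_unfold(Li, i), compute_uv=False).sum()
        for i, Li in enumerate(tensors)
    )
    return float(nuc + lam * np.abs(S).sum())


def horpca_singleton(
    A: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    mu: float | None = None,
    track_objective: bool = False,
    warn: bool = True,
) -> HoRPCADecomposition:
    """Low-rank + sparse decomposition of a tensor (Singleton model, ADAL).

    Parameters
    ----------
    A:
        Input tensor (any order >= 2).
    lam:
        Sparsity weight; defaults to ``1/sqrt(max(A.shape))``.
    mu:
        ADAL proximal parameter (also the SVT threshold); defaults to
        ``10 / sigma_1`` where ``sigma_1`` is the largest singular value
        over all unfoldings of ``A``.  Fixed (non-adaptive) throughout.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite input tensor")
    N = A.ndim
    if lam is None:
        lam = default_lambda(A.shape)
    if not lam > 0:
        raise ValueError("lambda must be positive")
    normA = np.linalg.norm(A)
    if normA == 0:
        return HoRPCADecomposition(np.zeros_like(A), np.zeros_like(A), lam, 0, 0.0, True)
    if mu is None:
        sigma1 = max(
            np.linalg.norm(mode_unfold(A, i), ord=2) for i in range(N)
        )
        mu = 10.0 / sigma1

    L_aux = [np.zeros_like(A) for _ in range(N)]
    S = np.zeros_like(A)
    duals = [np.zeros_like(A) for _ in range(N)]
    history: list[float] = []
    fp_history: list[float] = []
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        S_prev = S
        L_prev = L_aux
        L_aux = [
            mode_fold(svt(mode_unfold(A - S + mu * duals[i], i), mu), i, A.shape)
            for i in range(N)
        ]
        mean_target = np.mean(
            [A - L_aux[i] + mu * duals[i] for i in range(N)], axis=0
        )
        S = soft_threshold(mean_target, lam * mu / N)
        resid_sq = 0.0
        for i in range(N):
            r = L_aux[i] + S - A
            duals[i] = duals[i] - r / mu
            resid_sq += float(np.sum(r * r))
        resid = np.sqrt(resid_sq) / (np.sqrt(N) * normA)
        dual_resid = np.linalg.norm(S - S_prev) / normA
        fp_sq = float(np.sum((S - S_prev) ** 2)) + sum(
            float(np.sum((L_aux[i] - L_prev[i]) ** 2)) for i in range(N)
        )
        fp_history.append(np.sqrt(fp_sq) / normA)
        if track_objective:
            history.append(_objective(L_aux, S, lam))
        if resid <= tol and dual_resid <= tol:
            break
    converged = resid <= tol
    if not converged and warn:
        warnings.warn(
            f"HoRPCA did not converge in {max_iter} iterations "
            f"(relative residual {resid:.2e})",
            RuntimeWarning,
        )
    L = np.mean(L_aux, axis=0)
    return HoRPCADecomposition(
        low_rank=L,
        sparse=S,
        lam=float(lam),
        iterations=it,
        primal_residual=float(resid),
        converged=bool(converged),
        objective_history=np.asarray(history),
        fixed_point_history=np.asarray(fp_history),
    )
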