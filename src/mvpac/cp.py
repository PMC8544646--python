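"""Nonnegative CANDECOMP/PARAFAC comparator with DIFFIT rank selection.

Fits ``A[i,j,k,l] ~= sum_r lambda_r a_ir b_jr c_kr d_lr`` with all factors
nonnegative, by HALS-style alternating nonnegative least squares.  The rank
is chosen by the DIFference-in-FIT heuristic, and coupled channel pairs are
read off the peaks of the first two spatial factor vectors screened against
band-averaged surrogate thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .horpca import mode_unfold

__all__ = ["CPModel", "nncp_decompose", "diffit_rank", "parafac_detect_pairs"]


@dataclass
class CPModel:
    """Nonnegative CP model with unit-norm factor columns.

    ``factors`` holds one ``(I_n, R)`` matrix per mode; column norms are
    absorbed into ``weights``.  ``fit`` is the percentage of explained
    variation, ``100 * (1 - ||A - Ahat||_F / ||A||_F)``.
    """

    weights: np.ndarray
    factors: list[np.ndarray]
    fit: float
    #: relative reconstruction error after each ALS sweep
    error_history: np.ndarray = None  # type: ignore[assignment]

    @property
    def rank(self) -> int:
        return self.weights.size

    def dense(self) -> np.ndarray:
        shape = tuple(f.shape[0] for f in self.factors)
        out = np.zeros(shape)
        for r in range(self.rank):
            outer = self.factors[0][:, r] * self.weights[r]
            for f in self.factors[1:]:
                outer = np.multiply.outer(outer, f[:, r])
            out += outer
        return out


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def _fit_pct(A: np.ndarray, model_dense: np.ndarray, normA: float) -> float:
    return float(100.0 * (1.0 - np.linalg.norm(A - model_dense) / normA))


def nncp_decompose(
    A: np.ndarray,
    R: int,
    tol: float = 1e-7,
    max_iter: int = 200,
    rng_seed: int | np.random.Generator | None = 0,
    n_restarts: int = 5,
) -> CPModel:
    """Nonnegative CP via HALS with random restarts (best fit kept)."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("input tensor must be nonnegative")
    if R < 1:
        raise ValueError("rank must be >= 1")
    if R > min(np.prod(A.shape) // max(A.shape), max(A.shape)) * max(A.shape):
        raise ValueError("rank unreasonably large for tensor shape")
    normA = np.linalg.norm(A)
    if normA == 0:
        factors = [np.zeros((s, R)) for s in A.shape]
        return CPModel(weights=np.zeros(R), factors=factors, fit=100.0)
    rng = np.random.default_rng(rng_seed)
    best: CPModel | None = None
    unfolds = [mode_unfold(A, n) for n in range(A.ndim)]
    for _ in range(n_restarts):
        model = _nncp_single(A, unfolds, R, tol, max_iter, rng, normA)
        if best is None or model.fit > best.fit:
            best = model
    assert best is not None
    return best


def _nncp_single(A, unfolds, R, tol, max_iter, rng, normA) -> CPModel:
    N = A.ndim
    factors = [np.abs(rng.standard_normal((s, R))) + 1e-3 for s in A.shape]
    prev_err = np.inf
    err_history: list[float] = []
    for sweep in range(max_iter):
        # revive dead components (a zeroed column locks itself out of every
        # HALS update); the reseed magnitude is negligible so the sweep-level
        # error stays monotone, while the next update rescales the column
        if sweep < 0.8 * max_iter:
            col_norms = [np.linalg.norm(f, axis=0) for f in factors]
            for r in range(R):
                if any(cn[r] < 1e-12 for cn in col_norms):
                    for n in range(N):
                        col = rng.random(A.shape[n]) + 0.1
                        factors[n][:, r] = col / np.linalg.norm(col)
                    # keep the revived component's contribution negligible;
                    # the mode-0 update rescales it against an O(1) Gram
                    factors[0][:, r] *= 1e-9 * normA
        for n in range(N):
            others = [factors[m] for m in range(N) if m != n]
            kr = _khatri_rao(others)
            gram = np.ones((R, R))
            for m in range(N):
                if m != n:
                    gram *= factors[m].T @ factors[m]
            mttkrp = unfolds[n] @ kr
            # HALS: cyclic nonnegative column updates
            F = factors[n]
            for r in range(R):
                num = mttkrp[:, r] - F @ gram[:, r] + F[:, r] * gram[r, r]
                denom = gram[r, r]
                if denom <= 1e-14:
                    F[:, r] = 0.0
                else:
                    F[:, r] = np.maximum(num / denom, 0.0)
            factors[n] = F
        err = _rel_err(unfolds[0], factors, normA)
        err_history.append(err)
        if np.isfinite(prev_err) and abs(prev_err - err) <= tol * max(err, 1e-12):
            prev_err = err
            break
        prev_err = err
    # normalise columns, absorb norms into weights
    weights = np.ones(R)
    for n in range(N):
        norms = np.linalg.norm(factors[n], axis=0)
        norms_safe = np.where(norms > 0, norms, 1.0)
        factors[n] = factors[n] / norms_safe
        weights *= norms
    order = np.argsort(weights)[::-1]
    weights = weights[order]
    factors = [f[:, order] for f in factors]
    fit = 100.0 * (1.0 - prev_err)
    return CPModel(
        weights=weights,
        factors=factors,
        fit=float(fit),
        error_history=np.asarray(err_history),
    )


def _rel_err(unfold0, factors, normA) -> float:
    kr = _khatri_rao(factors[1:])
    approx = factors[0] @ kr.T
    return float(np.linalg.norm(unfold0 - approx) / normA)


def diffit_rank(
    A: np.ndarray,
    R_max: int = 6,
    noise_floor: float = 0.05,
    rng_seed: int | None = 0,
    **cp_kwargs,
) -> tuple[int, np.ndarray]:
    """DIFFIT rank selection.

    Fits models for ``R = 1..R_max``; with ``DIF(R) = fit(R) - fit(R-1)``
    and ``DIFFIT(R) = DIF(R)/DIF(R+1)``, returns the argmax of DIFFIT over
    ``2..R_max-1`` together with the fit table.  If successive fits change
    by less than ``noise_floor`` percentage points the smallest such rank is
    returned instead (degenerate-denominator fallback).
    """
    if R_max < 3:
        raise ValueError("R_max must be >= 3")
    fits = np.array(
        [nncp_decompose(A, R, rng_seed=rng_seed, **cp_kwargs).fit for R in range(1, R_max + 1)]
    )
    dif = np.diff(fits)  # DIF(R) for R = 2..R_max
    small = np.where(dif < noise_floor)[0]
    if small.size:
        return int(small[0] + 1), fits
    diffit = dif[:-1] / dif[1:]  # DIFFIT(R) for R = 2..R_max-1
    return int(np.argmax(diffit) + 2), fits


def factor_peaks(vec: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Indices whose loading exceeds ``mean + n_sd * sd`` of the vector.

    A (near-)flat vector has no peaks.
    """
    vec = np.asarray(vec, dtype=float)
    sd = vec.std()
    if sd < 1e-12 * max(np.abs(vec).max(), 1e-300):
        return np.empty(0, dtype=int)
    return np.where(vec >= vec.mean() + n_sd * sd)[0]


def parafac_detect_pairs(
    model: CPModel,
    thresholds: np.ndarray | None = None,
    adjacency: np.ndarray | None = None,
    n_sd: float = 2.0,
) -> set[tuple[int, int, int]]:
    """Coupled (phase channel, amplitude channel, band) triples from CP factors.

    Takes the component with the largest weight; phase channels are peaks of
    its first-mode factor, amplitude channels peaks of the second-mode
    factor, and the band the peak of the third-mode factor.  The resulting
    ``P x Q`` outer-product candidates are screened against band-averaged
    thresholds (``thresholds[i, j, band]``) using the subject-averaged
    network ``adjacency[i, j, band]`` when both are given.
    """
    r = int(np.argmax(model.weights))
    a, b, c = model.factors[0][:, r], model.factors[1][:, r], model.factors[2][:, r]
    pa, pb = factor_peaks(a, n_sd), factor_peaks(b, n_sd)
    if pa.size == 0 or pb.size == 0:
        warnings.warn("flat CP factors: no peaks above mean + 2 sd", RuntimeWarning)
        return set()
    band = int(np.argmax(c))
    candidates = {(int(i), int(j), band) for i in pa for j in pb}
    if thresholds is None or adjacency is None:
        return candidates
    return {
        (i, j, m)
        for (i, j, m) in candidates
        if adjacency[i, j, m] > thresholds[i, j, m]
    }
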