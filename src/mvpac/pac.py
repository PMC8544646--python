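"""Trial-ensemble modulation index and surrogate significance testing.

The amplitude-normalised modulation index of a K-trial ensemble is

    MI(t) = (1/sqrt(K)) |sum_k A_k(t) exp(j phi_k(t))| / sqrt(sum_k A_k(t)^2)

which lies in [0, 1] by Cauchy-Schwarz.  Significance thresholds come from a
block-swap surrogate null: each trial's amplitude series is split at a random
interior point, the two halves are swapped (a circular rotation), the
time-averaged MI is recomputed, and the (1 - alpha) empirical quantile over
``n_surrogates`` repetitions is the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialEnsemble",
    "PACSeries",
    "ThresholdTable",
    "modulation_index",
    "time_average_mi",
    "surrogate_threshold",
    "band_average_threshold",
    "surrogate_thresholds_bulk",
]

DEFAULT_N_SURROGATES = 100
DEFAULT_ALPHA = 0.05


@dataclass
class TrialEnsemble:
    """K trials x T samples of one channel."""

    data: np.ndarray
    fs: float
    channel_id: str | int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("ensemble must be a K x T array with K >= 1")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PACSeries:
    """Time-resolved modulation index for one (f_p, f_a) pair."""

    mi: np.ndarray
    f_p: float
    f_a: float


@dataclass
class ThresholdTable:
    """Surrogate thresholds over (phase channel, amplitude channel, f_p, f_a)."""

    th: np.ndarray
    f_p_axis: np.ndarray
    f_a_axis: np.ndarray
    n_surrogates: int = DEFAULT_N_SURROGATES
    alpha: float = DEFAULT_ALPHA


def modulation_index(amps: np.ndarray, phases: np.ndarray, f_p: float = np.nan, f_a: float = np.nan) -> PACSeries:
    """Amplitude-normalised modulation index of a trial ensemble.

    Parameters
    ----------
    amps:
        Nonnegative amplitudes, shape ``(K, T)``.
    phases:
        Phases in radians, shape ``(K, T)``.

    Time points where every trial's amplitude is zero get ``MI = 0``.
    """
    amps = np.asarray(amps, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amps.shape != phases.shape or amps.ndim != 2:
        raise ValueError("amps and phases must both have shape (K, T)")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be nonnegative")
    K = amps.shape[0]
    num = np.abs(np.sum(amps * np.exp(1j * phases), axis=0))
    den = np.sqrt(np.sum(amps**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = num / (np.sqrt(K) * den)
    mi = np.where(den > 0, mi, 0.0)
    # guard against roundoff pushing the Cauchy-Schwarz bound past 1
    return PACSeries(mi=np.clip(mi, 0.0, 1.0), f_p=f_p, f_a=f_a)


def time_average_mi(series: PACSeries, window: tuple[int, int] | None = None) -> float:
    """Mean MI over a half-open sample window ``[start, stop)``."""
    mi = series.mi
    if window is not None:
        start, stop = window
        mi = mi[start:stop]
    if mi.size == 0:
        raise ValueError("empty averaging window")
    return float(np.mean(mi))


def _swap_shifts(rng: np.random.Generator, n: int, K: int, T: int) -> np.ndarray:
    """Random split points mapped to circular shifts, one per (surrogate, trial).

    Splitting ``a = [a[:p], a[p:]]`` and swapping the halves equals rolling the
    series left by ``p``; the split point is drawn uniformly from the interior
    ``[ceil(0.1 T), floor(0.9 T)]`` to avoid near-identity swaps.
    """
    lo = int(np.ceil(0.1 * T))
    hi = int(np.floor(0.9 * T))
    lo = max(lo, 1)
    hi = min(hi, T - 1)
    if hi < lo:
        raise ValueError("record too short to split")
    return rng.integers(lo, hi + 1, size=(n, K))


def surrogate_threshold(
    amps: np.ndarray,
    phases: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    alpha: float = DEFAULT_ALPHA,
    rng: np.random.Generator | int | None = None,
    window: tuple[int, int] | None = None,
) -> float:
    """Block-swap surrogate threshold for the time-averaged MI.

    Returns the ``(1 - alpha)`` empirical quantile of ``n_surrogates``
    surrogate time-averaged MI values.
    """
    amps = np.asarray(amps, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amps.shape != phases.shape or amps.ndim != 2:
        raise ValueError("amps and phases must both have shape (K, T)")
    K, T = amps.shape
    if T < 4:
        raise ValueError("need at least 4 samples to block-swap")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(rng)
    vals = surrogate_mi_values(amps, phases, n_surrogates, rng, window)
    return float(np.quantile(vals, 1.0 - alpha))


def surrogate_mi_values(
    amps: np.ndarray,
    phases: np.ndarray,
    n_surrogates: int,
    rng: np.random.Generator,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """The raw surrogate time-averaged MI values (one per surrogate)."""
    K, T = amps.shape
    shifts = _swap_shifts(rng, n_surrogates, K, T)
    t = np.arange(T)
    idx = (t[None, None, :] + shifts[:, :, None]) % T  # (n, K, T)
    amps_s = amps[np.arange(K)[None, :, None], idx]
    ph = np.exp(1j * phases)
    num = np.abs(np.einsum("skt,kt->st", amps_s, ph))
    den = np.sqrt(np.einsum("skt,skt->st", amps_s, amps_s))
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = num / (np.sqrt(K) * den)
    mi = np.where(den > 0, mi, 0.0)
    if window is not None:
        mi = mi[:, window[0] : window[1]]
    return mi.mean(axis=1)


def surrogate_thresholds_bulk(
    amp_sets: np.ndarray,
    phase_sets: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    alpha: float = DEFAULT_ALPHA,
    rng: np.random.Generator | int | None = None,
    return_moments: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds for every (phase set, amplitude set) combination at once.

    Parameters
    ----------
    amp_sets:
        Amplitudes of shape ``(P, K, T)`` — e.g. one entry per (amplitude
        channel, f_a) combination.
    phase_sets:
        Phases of shape ``(Q, K, T)`` — one per (phase channel, f_p).

    Returns
    -------
    ``(Q, P)`` array of thresholds.  Surrogate shifts are drawn independently
    per amplitude set; within one amplitude set the same shifted amplitudes
    are screened against every phase set, which keeps the null marginally
    correct for each pair while amortising the shuffling cost.
    """
    amp_sets = np.asarray(amp_sets, dtype=float)
    phase_sets = np.asarray(phase_sets, dtype=float)
    P, K, T = amp_sets.shape
    Q = phase_sets.shape[0]
    rng = np.random.default_rng(rng)
    ph = np.exp(1j * phase_sets)  # (Q, K, T)
    out = np.empty((Q, P))
    mean = np.empty((Q, P))
    sd = np.empty((Q, P))
    t = np.arange(T)
    k_idx = np.arange(K)[None, :, None]
    ph_t = np.ascontiguousarray(
        ph.astype(np.complex64).transpose(2, 0, 1)
    )  # (T, Q, K)
    for p in range(P):
        shifts = _swap_shifts(rng, n_surrogates, K, T)
        idx = (t[None, None, :] + shifts[:, :, None]) % T
        amps_s = amp_sets[p][k_idx, idx]  # (n, K, T)
        den = np.sqrt(np.einsum("skt,skt->st", amps_s, amps_s))
        # batched over time: (T, Q, K) @ (T, K, n) -> (T, Q, n)
        amps_t = np.ascontiguousarray(
            amps_s.astype(np.complex64).transpose(2, 1, 0)
        )
        num = np.abs(ph_t @ amps_t).transpose(1, 2, 0)  # (Q, n, T)
        with np.errstate(invalid="ignore", divide="ignore"):
            mi = num / (np.sqrt(K) * den[None])
        mi = np.where(den[None] > 0, mi, 0.0)
        vals = mi.mean(axis=2)  # (Q, n)
        out[:, p] = np.quantile(vals, 1.0 - alpha, axis=1)
        mean[:, p] = vals.mean(axis=1)
        sd[:, p] = vals.std(axis=1)
    if return_moments:
        return out, mean, sd
    return out


def band_average_threshold(table: ThresholdTable, F_p, F_a, i: int | None = None, j: int | None = None) -> float | np.ndarray:
    """Mean threshold over all (f_p, f_a) pairs in the two bands.

    ``table.th`` may be 2-D ``(n_fp, n_fa)`` for a single channel pair or
    4-D ``(N, N, n_fp, n_fa)``; in the latter case a matrix is returned
    unless ``i``/``j`` are given.
    """
    F_p = np.atleast_1d(np.asarray(F_p, dtype=float))
    F_a = np.atleast_1d(np.asarray(F_a, dtype=float))
    sel_p = np.isin(np.round(table.f_p_axis, 6), np.round(F_p, 6))
    sel_a = np.isin(np.round(table.f_a_axis, 6), np.round(F_a, 6))
    if not sel_p.any() or not sel_a.any():
        raise ValueError("band has no frequencies on the threshold grid")
    th = table.th
    if th.ndim == 2:
        sub = th[np.ix_(sel_p, sel_a)]
        return float(sub.mean())
    sub = th[:, :, sel_p, :][:, :, :, sel_a]
    avg = sub.mean(axis=(2, 3))
    if i is not None and j is not None:
        return float(avg[i, j])
    return avg
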