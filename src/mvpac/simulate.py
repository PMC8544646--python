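"""Synthetic multi-channel EEG with ground-truth phase-amplitude coupling.

Per subject the generator produces power-law (Brownian by default) dipole
time series with imposed cross-dipole correlation, replaces selected dipole
pairs with monophasic coupled oscillations (bursts of band-limited high
frequency activity gated by a DC-shifted Hanning window placed at the peaks
of the low-frequency signal), projects to scalp channels through a lead
field, and adds white Gaussian measurement noise at a configured SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows

__all__ = [
    "Coupling",
    "SimulationConfig",
    "LeadField",
    "SyntheticDataset",
    "colored_noise",
    "impose_cross_correlation",
    "inject_pac",
    "forward_project",
    "add_noise",
    "spherical_lead_field",
    "generate_dataset",
]

#: duration of the coupling (Hanning) window, seconds
COUPLING_WINDOW_S = 0.042
#: DC shift of the modulation envelope
DC_SHIFT = 0.1


@dataclass(frozen=True)
class Coupling:
    """One planted directed coupling between two dipoles."""

    phase_dipole: int
    amp_dipole: int
    f_p: float
    f_a: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("coupling intensity must be in [0, 1]")
        if not self.f_p + 1 < self.f_a - 5:
            raise ValueError("phase and amplitude bands must not overlap")


@dataclass
class SimulationConfig:
    fs: float = 128.0
    duration: float = 1.0
    n_dipoles: int = 16
    n_channels: int = 16
    n_trials: int = 16
    n_subjects: int = 10
    beta: float = 2.0
    couplings: list[Coupling] = field(default_factory=list)
    snr_db: float | None = 6.0
    variability_fraction: float = 0.0
    cross_corr: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.variability_fraction <= 1.0:
            raise ValueError("variability_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class LeadField:
    """Linear gain from dipoles to scalp channels."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be a channels x dipoles matrix")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        if np.any(np.all(self.gain == 0, axis=1)):
            raise ValueError("gain has an all-zero channel row")

    def dominant_channel(self, dipole: int) -> int:
        return int(np.argmax(np.abs(self.gain[:, dipole])))


@dataclass
class SyntheticDataset:
    """Per-subject channel data plus the ground-truth coupling manifest."""

    data: np.ndarray  # (S, n_channels, K, T)
    truth: list[list[tuple[int, int, str]]]  # per subject: (phase_ch, amp_ch, band)
    couplings: list[list[Coupling]]  # per subject, dipole-space manifest
    config: SimulationConfig = None  # type: ignore[assignment]
    lead_field: LeadField = None  # type: ignore[assignment]

    @property
    def fs(self) -> float:
        return self.config.fs

    def truth_set(self, band_order: list[str]) -> set[tuple[int, int, int]]:
        """Union of per-subject truths as (i, j, band-index) triples."""
        out = set()
        for subj in self.truth:
            for i, j, band in subj:
                out.add((i, j, band_order.index(band)))
        return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + np.sqrt(5)) * k
    return np.c_[
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ]


def spherical_lead_field(
    n_channels: int, n_dipoles: int, depth: float = 0.85, offset: float = 0.05
) -> LeadField:
    """Synthetic volume-conduction geometry on the unit sphere.

    Channels sit on the unit sphere; dipoles at radius ``depth``.  When the
    counts match, dipole ``d`` sits under channel ``d`` so every dipole has a
    well-defined dominant channel.  Gain decays as ``1 / (offset + r^2)``.
    """
    ch = _fibonacci_sphere(n_channels)
    if n_dipoles == n_channels:
        dip = depth * ch
    elif n_dipoles > n_channels:
        # first n_channels dipoles sit under their channels; spares fill a
        # rotated shell of their own so they interleave with the paired ones
        extra = _fibonacci_sphere(n_dipoles - n_channels)
        rot = np.array(
            [[np.cos(0.7), -np.sin(0.7), 0], [np.sin(0.7), np.cos(0.7), 0], [0, 0, 1]]
        )
        dip = depth * np.vstack([ch, extra @ rot.T])
    else:
        dip = depth * _fibonacci_sphere(n_dipoles)
    d2 = ((ch[:, None, :] - dip[None, :, :]) ** 2).sum(axis=2)
    return LeadField(gain=1.0 / (offset + d2))


def colored_noise(
    T: int, fs: float, beta: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Zero-mean unit-variance noise with power spectrum ``~ 1/f**beta``."""
    rng = np.random.default_rng(rng)
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=T)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def impose_cross_correlation(
    X: np.ndarray,
    target_corr: np.ndarray,
    repair: bool = False,
) -> np.ndarray:
    """Mix rows of ``X`` (dipoles x samples) to the target correlation.

    Uses the eigendecomposition ``target = V D V^T`` and returns
    ``V D^(1/2) V^T... @ X`` — more precisely the coloring transform
    ``(V sqrt(D)) X`` whose output covariance is the target for white input.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(target_corr, dtype=float)
    if C.shape != (X.shape[0], X.shape[0]) or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target correlation must be symmetric, matching X rows")
    w, V = np.linalg.eigh(C)
    if np.any(w < -1e-10):
        if not repair:
            raise ValueError("target correlation is not positive semi-definite")
        w = np.clip(w, 0.0, None)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ (V.T @ X)


def random_correlation(
    n: int, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Random PSD correlation matrix with mean off-diagonal ~ ``strength``."""
    k = max(1, int(np.ceil(n * strength * 2)))
    B = rng.standard_normal((n, k))
    C = B @ B.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    out = strength * C + (1 - strength) * np.eye(n)
    np.fill_diagonal(out, 1.0)
    return out


def bandpass(x: np.ndarray, f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Zero-phase brick-wall band-pass via the real FFT."""
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    X[(f < f_lo) | (f > f_hi)] = 0.0
    return np.fft.irfft(X, n=x.size)


def _relative_maxima(x: np.ndarray) -> np.ndarray:
    s = np.convolve(x, np.ones(3) / 3.0, mode="same")
    return np.where((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:]))[0] + 1


def inject_pac(
    base: np.ndarray,
    f_p: float,
    f_a: float,
    intensity: float,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monophasic burst coupling generated from a common base signal.

    Returns ``(x_fp, x_fa, envelope)``: the low-frequency phase signal
    (band-pass ``f_p`` +/- 1 Hz), the coupled high-frequency signal (band-pass
    ``f_a`` +/- 5 Hz carrier times the burst envelope), and the envelope
    itself.  The envelope is ``DC_SHIFT + intensity * hann(42 ms)`` summed at
    the relative maxima of the phase signal, saturated at
    ``DC_SHIFT + intensity``; both outputs are scaled to unit variance.
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    base = np.asarray(base, dtype=float)
    T = base.size
    x_fp = bandpass(base, f_p - 1.0, f_p + 1.0, fs)
    carrier = bandpass(base, f_a - 5.0, f_a + 5.0, fs)
    L = max(3, int(round(COUPLING_WINDOW_S * fs)))
    win = windows.hann(L)
    env = np.zeros(T)
    for peak in _relative_maxima(x_fp):
        lo = peak - L // 2
        a, b = max(lo, 0), min(lo + L, T)
        env[a:b] += intensity * win[a - lo : b - lo]
    env = DC_SHIFT + np.minimum(env, intensity)
    x_fa = carrier * env
    for arr in (x_fp, x_fa):
        sd = arr.std()
        if sd > 0:
            arr /= sd
    return x_fp, x_fa, env


def forward_project(dipole_data: np.ndarray, lead: LeadField) -> np.ndarray:
    """Apply the lead-field gain: channels = gain @ dipoles (first axis)."""
    dipole_data = np.asarray(dipole_data, dtype=float)
    if dipole_data.shape[0] != lead.gain.shape[1]:
        raise ValueError(
            f"dipole axis {dipole_data.shape[0]} does not match lead field "
            f"with {lead.gain.shape[1]} dipoles"
        )
    return np.tensordot(lead.gain, dipole_data, axes=(1, 0))


def add_noise(
    channel_data: np.ndarray, snr_db: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Additive white Gaussian noise at the given per-channel SNR (dB)."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(rng)
    x = np.asarray(channel_data, dtype=float)
    power = np.mean(x**2, axis=-1, keepdims=True)
    if np.any(power == 0):
        raise ValueError("zero-power channel: SNR undefined")
    noise_sd = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return x + noise_sd * rng.standard_normal(x.shape)


def band_of(f_p: float) -> str:
    """Name of the canonical low band containing ``f_p``."""
    if 1 <= f_p <= 3:
        return "delta-gamma"
    if 4 <= f_p <= 7:
        return "theta-gamma"
    if 8 <= f_p <= 12:
        return "alpha-gamma"
    if 13 <= f_p <= 30:
        return "beta-gamma"
    raise ValueError(f"f_p={f_p} outside the canonical low bands")


def _vary_couplings(
    couplings: list[Coupling],
    fraction: float,
    n_dipoles: int,
    rng: np.random.Generator,
) -> list[Coupling]:
    """Re-draw ``fraction`` of the coupled dipole locations.

    Replacement dipoles come from the unused pool when one exists; when every
    dipole is already an endpoint (the dense desk-scale geometry) the selected
    endpoints exchange their dipoles instead, which relocates the same number
    of coupling endpoints.
    """
    if fraction <= 0 or not couplings:
        return list(couplings)
    n_locs = int(round(fraction * 2 * len(couplings)))
    if n_locs == 0:
        return list(couplings)
    used = {c.phase_dipole for c in couplings} | {c.amp_dipole for c in couplings}
    free = [d for d in range(n_dipoles) if d not in used]
    rng.shuffle(free)
    slots = [(i, end) for i in range(len(couplings)) for end in ("phase", "amp")]
    n_locs = min(max(n_locs, 2 if not free else 1), len(slots))
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_locs, replace=False)]
    out = list(couplings)

    def _get(idx, end):
        c = out[idx]
        return c.phase_dipole if end == "phase" else c.amp_dipole

    def _set(idx, end, dipole):
        c = out[idx]
        out[idx] = (
            replace(c, phase_dipole=dipole)
            if end == "phase"
            else replace(c, amp_dipole=dipole)
        )

    if free:
        for idx, end in chosen:
            if not free:
                break
            old = _get(idx, end)
            _set(idx, end, free.pop())
            free.insert(int(rng.integers(len(free) + 1)), old)
    else:
        dipoles = [_get(idx, end) for idx, end in chosen]
        for _ in range(20):
            rotated = list(dipoles)
            rng.shuffle(rotated)
            trial = list(out)
            for (idx, end), dipole in zip(chosen, rotated):
                c = trial[idx]
                trial[idx] = (
                    replace(c, phase_dipole=dipole)
                    if end == "phase"
                    else replace(c, amp_dipole=dipole)
                )
            moved = sum(d != r for d, r in zip(dipoles, rotated))
            degenerate = any(c.phase_dipole == c.amp_dipole for c in trial)
            if not degenerate and moved >= max(1, len(chosen) - 1):
                out = trial
                break
    return out


def generate_dataset(cfg: SimulationConfig, lead: LeadField | None = None) -> SyntheticDataset:
    """Generate the full multi-subject dataset described by ``cfg``."""
    for c in cfg.couplings:
        if not (0 <= c.phase_dipole < cfg.n_dipoles and 0 <= c.amp_dipole < cfg.n_dipoles):
            raise ValueError(f"coupling dipole indices out of range: {c}")
    rng = np.random.default_rng(cfg.rng_seed)
    lead = lead or spherical_lead_field(cfg.n_channels, cfg.n_dipoles)
    T, K = cfg.n_samples, cfg.n_trials
    data = np.empty((cfg.n_subjects, cfg.n_channels, K, T))
    truth: list[list[tuple[int, int, str]]] = []
    manifests: list[list[Coupling]] = []
    for s in range(cfg.n_subjects):
        subj_couplings = _vary_couplings(
            cfg.couplings, cfg.variability_fraction, cfg.n_dipoles, rng
        )
        corr = random_correlation(cfg.n_dipoles, cfg.cross_corr, rng)
        for k in range(K):
            X = np.stack(
                [colored_noise(T, cfg.fs, cfg.beta, rng) for _ in range(cfg.n_dipoles)]
            )
            X = impose_cross_correlation(X, corr)
            for c in subj_couplings:
                base = colored_noise(T, cfg.fs, cfg.beta, rng)
                x_fp, x_fa, _ = inject_pac(base, c.f_p, c.f_a, c.intensity, cfg.fs)
                X[c.phase_dipole] = x_fp
                X[c.amp_dipole] = x_fa
            # noise enters at the dipole level, before projection
            if cfg.snr_db is not None:
                X = add_noise(X, cfg.snr_db, rng)
            data[s, :, k, :] = forward_project(X, lead)
        manifests.append(subj_couplings)
        truth.append(
            [
                (
                    lead.dominant_channel(c.phase_dipole),
                    lead.dominant_channel(c.amp_dipole),
                    band_of(c.f_p),
                )
                for c in subj_couplings
                if c.intensity > 0
            ]
        )
    return SyntheticDataset(
        data=data, truth=truth, couplings=manifests, config=cfg, lead_field=lead
    )
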