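"""Assembly of significant PAC values into directed networks and 4-way tensors.

A network entry ``adjacency[i, j]`` is the band-averaged, surrogate-gated
modulation index computed from the phase of channel ``i`` and the amplitude of
channel ``j`` (directed, diagonal retained).  Networks for ``M`` band pairs
and ``S`` subjects stack into a nonnegative tensor of shape ``(N, N, M, S)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandPair",
    "PACNetwork",
    "PACTensor",
    "DEFAULT_BAND_PAIRS",
    "significant_mi",
    "band_average_network",
    "build_pac_tensor",
]


@dataclass(frozen=True)
class BandPair:
    """A low-frequency band modulating a high-frequency band.

    ``f_p`` / ``f_a`` list the sampled frequencies (Hz) used on the MI grid.
    """

    name: str
    f_p: tuple[float, ...]
    f_a: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.f_p or not self.f_a:
            raise ValueError("band pair needs at least one frequency per band")
        if max(self.f_p) >= min(self.f_a):
            raise ValueError("low band must lie strictly below high band")


def default_band_pairs(
    f_p_lists: dict[str, tuple[float, ...]] | None = None,
    gamma: tuple[float, ...] = tuple(range(31, 101)),
) -> list[BandPair]:
    """The four default low bands (delta, theta, alpha, beta) vs gamma.

    Band order is fixed: delta-gamma, theta-gamma, alpha-gamma, beta-gamma —
    so theta-gamma is slice index 1 (0-based).
    """
    lows = f_p_lists or {
        "delta": tuple(range(1, 4)),
        "theta": tuple(range(4, 8)),
        "alpha": tuple(range(8, 13)),
        "beta": tuple(range(13, 31)),
    }
    return [BandPair(f"{name}-gamma", tuple(fp), tuple(gamma)) for name, fp in lows.items()]


DEFAULT_BAND_PAIRS = default_band_pairs()
#: 0-based index of the theta-gamma slice in the default band order
THETA_GAMMA_INDEX = 1


@dataclass
class PACNetwork:
    """Directed weighted coupling network for one band pair and subject."""

    adjacency: np.ndarray
    band_pair: BandPair
    subject_id: str | int = 0

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency entries must be nonnegative")


@dataclass
class PACTensor:
    """Nonnegative 4-way array: phase channel x amp channel x band pair x subject."""

    values: np.ndarray
    channel_labels: list = field(default_factory=list)
    band_labels: list = field(default_factory=list)
    subject_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("PAC tensor must be 4-way")
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("first two modes must both equal the channel count")
        if np.any(self.values < 0):
            raise ValueError("PAC tensor must be nonnegative")
        n, _, m, s = self.values.shape
        if not self.channel_labels:
            self.channel_labels = list(range(n))
        if not self.band_labels:
            self.band_labels = list(range(m))
        if not self.subject_labels:
            self.subject_labels = list(range(s))
        if (
            len(self.channel_labels) != n
            or len(self.band_labels) != m
            or len(self.subject_labels) != s
        ):
            raise ValueError("label lengths inconsistent with tensor shape")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape


def significant_mi(mi: np.ndarray, th: np.ndarray) -> np.ndarray:
    """Gate MI values by surrogate thresholds (strictly greater survives)."""
    mi = np.asarray(mi, dtype=float)
    th = np.asarray(th, dtype=float)
    if mi.shape != th.shape:
        raise ValueError(f"grid mismatch: mi {mi.shape} vs th {th.shape}")
    return np.where(mi > th, mi, 0.0)


def band_average_network(
    mi_star: np.ndarray,
    band: BandPair,
    f_p_axis,
    f_a_axis,
    subject_id: str | int = 0,
) -> PACNetwork:
    """Average gated MI over a band pair's frequency grid for all channel pairs.

    Parameters
    ----------
    mi_star:
        Gated MI of shape ``(N, N, n_fp, n_fa)`` (phase channel, amplitude
        channel, low frequency, high frequency).
    """
    mi_star = np.asarray(mi_star, dtype=float)
    f_p_axis = np.asarray(f_p_axis, dtype=float)
    f_a_axis = np.asarray(f_a_axis, dtype=float)
    sel_p = np.isin(np.round(f_p_axis, 6), np.round(band.f_p, 6))
    sel_a = np.isin(np.round(f_a_axis, 6), np.round(band.f_a, 6))
    if not sel_p.any() or not sel_a.any():
        raise ValueError(f"band {band.name} has no frequencies on the MI grid")
    sub = mi_star[:, :, sel_p, :][:, :, :, sel_a]
    return PACNetwork(adjacency=sub.mean(axis=(2, 3)), band_pair=band, subject_id=subject_id)


def build_pac_tensor(networks: list[PACNetwork]) -> PACTensor:
    """Stack per-(band, subject) networks into the 4-way PAC tensor.

    Requires a complete band x subject grid with identical channel counts.
    Band order follows first appearance; subjects are sorted by label.
    """
    if not networks:
        raise ValueError("no networks supplied")
    n = networks[0].adjacency.shape[0]
    band_names: list[str] = []
    for net in networks:
        if net.adjacency.shape[0] != n:
            raise ValueError("all networks must share the channel count")
        if net.band_pair.name not in band_names:
            band_names.append(net.band_pair.name)
    subjects = sorted({net.subject_id for net in networks}, key=str)
    index = {(net.band_pair.name, net.subject_id): net for net in networks}
    missing = [
        (b, s) for b in band_names for s in subjects if (b, s) not in index
    ]
    if missing:
        raise ValueError(f"missing network slices for (band, subject): {missing}")
    values = np.zeros((n, n, len(band_names), len(subjects)))
    for bi, b in enumerate(band_names):
        for si, s in enumerate(subjects):
            values[:, :, bi, si] = index[(b, s)].adjacency
    return PACTensor(
        values=values,
        band_labels=band_names,
        subject_labels=list(subjects),
    )
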