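"""Recording ingestion (EDF/BDF), HDF5 persistence and run configuration.

The EDF/BDF reader implements the fixed-layout ASCII header plus 16-bit
(EDF) / 24-bit (BDF) little-endian sample records — enough to ingest
standard continuous exports; a matching writer exists primarily so tests can
round-trip synthetic fixtures without binary files in the repository.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .networks import PACTensor
from .pac import TrialEnsemble

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "load_recording",
    "save_tensor",
    "load_tensor",
    "save_decomposition",
    "load_decomposition",
    "write_manifest",
]

FORMAT_VERSION = "mvpac-h5-1"

_KNOWN_KEYS = {
    "tfd": {"sigma", "n_freq_bins"},
    "pac": {"n_surrogates", "alpha", "window_start", "window_stop"},
    "simulate": {
        "fs",
        "duration",
        "n_dipoles",
        "n_channels",
        "n_trials",
        "n_subjects",
        "beta",
        "snr_db",
        "variability_fraction",
        "cross_corr",
        "couplings",
    },
    "horpca": {"lambda", "lambda_literal", "tol", "max_iter", "mu"},
    "parafac": {"rank", "r_max", "tol", "max_iter", "n_restarts"},
    "experiments": {"n_repetitions", "methods", "sweep", "conditions"},
    "classify": {"n_folds", "n_repetitions", "band_index"},
}


@dataclass
class RunConfig:
    """Validated run configuration (rejects unknown keys)."""

    rng_seed: int = 0
    output_dir: str = "."
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {}
        seed = 0
        outdir = "."
        for key, value in raw.items():
            if key == "rng_seed":
                seed = int(value)
            elif key == "output_dir":
                outdir = str(value)
            elif key in _KNOWN_KEYS and isinstance(_KNOWN_KEYS[key], set):
                unknown = set(value) - _KNOWN_KEYS[key]
                if unknown:
                    raise ValueError(
                        f"unknown config keys in section {key!r}: {sorted(unknown)}"
                    )
                sections[key] = dict(value)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(rng_seed=seed, output_dir=outdir, sections=sections)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        stages = [
            "simulate",
            "pac",
            "build-tensor",
            "decompose",
            "parafac",
            "experiment1",
            "experiment2",
            "classify",
        ]
        offset = stages.index(stage) if stage in stages else len(stages)
        return int(
            np.random.SeedSequence([self.rng_seed, offset]).generate_state(1)[0]
        )


# ---------------------------------------------------------------------------
# EDF / BDF


def _pad(text: str, n: int) -> bytes:
    return text[:n].ljust(n).encode("ascii")


def write_recording(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str] | None = None,
    fmt: str = "EDF",
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
) -> None:
    """Write ``data`` (channels x samples) as a single-record-per-second file."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    labels = channel_labels or [f"ch{c}" for c in range(n_ch)]
    spr = int(round(fs))
    if n_samp % spr:
        raise ValueError("sample count must be a whole number of 1 s records")
    n_rec = n_samp // spr
    pmin, pmax = physical_range
    if fmt.upper() == "EDF":
        dmin, dmax = -32768, 32767
        version = _pad("0", 8)
        reserved = _pad("", 44)
    elif fmt.upper() == "BDF":
        dmin, dmax = -8388608, 8388607
        version = b"\xffBIOSEMI"
        reserved = _pad("24BIT", 44)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    header = bytearray()
    header += version
    header += _pad("synthetic", 80)
    header += _pad("mvpac fixture", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += reserved
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_ch), 4)
    for text, width in [
        (labels, 16),
        (["" for _ in labels], 80),
        (["uV" for _ in labels], 8),
        ([repr(pmin) for _ in labels], 8),
        ([repr(pmax) for _ in labels], 8),
        ([str(dmin) for _ in labels], 8),
        ([str(dmax) for _ in labels], 8),
        (["" for _ in labels], 80),
        ([str(spr) for _ in labels], 8),
        (["" for _ in labels], 32),
    ]:
        for item in text:
            header += _pad(item, width)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * scale + dmin), dmin, dmax).astype(
        np.int64
    )
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            if fmt.upper() == "EDF":
                fh.write(chunk.astype("<i2").tobytes())
            else:
                as32 = chunk.astype("<i4").tobytes()
                arr = np.frombuffer(as32, dtype=np.uint8).reshape(-1, 4)
                fh.write(arr[:, :3].tobytes())


def read_recording(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF or BDF file; returns (channels x samples, fs, labels)."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 256:
        raise ValueError(f"{path}: truncated header")
    version = blob[:8]
    is_bdf = version[0] == 0xFF
    try:
        n_rec = int(blob[236:244].decode("ascii").strip())
        rec_dur = float(blob[244:252].decode("ascii").strip())
        n_ch = int(blob[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise ValueError(f"{path}: malformed EDF/BDF header ({exc})") from exc
    off = 256
    fields = {}
    for name, width in [
        ("label", 16),
        ("transducer", 80),
        ("dim", 8),
        ("pmin", 8),
        ("pmax", 8),
        ("dmin", 8),
        ("dmax", 8),
        ("prefilter", 80),
        ("spr", 8),
        ("reserved", 32),
    ]:
        fields[name] = [
            blob[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]
        off += n_ch * width
    labels = fields["label"]
    spr = [int(s) for s in fields["spr"]]
    if len(set(spr)) != 1:
        raise ValueError(f"{path}: mixed per-channel sampling rates unsupported")
    fs = spr[0] / rec_dur
    pmin = np.array([float(x) for x in fields["pmin"]])
    pmax = np.array([float(x) for x in fields["pmax"]])
    dmin = np.array([float(x) for x in fields["dmin"]])
    dmax = np.array([float(x) for x in fields["dmax"]])

    bps = 3 if is_bdf else 2
    body = blob[off:]
    expected = n_rec * n_ch * spr[0] * bps
    if len(body) < expected:
        raise ValueError(f"{path}: truncated data section")
    out = np.empty((n_ch, n_rec * spr[0]))
    rec_bytes = n_ch * spr[0] * bps
    for r in range(n_rec):
        rec = body[r * rec_bytes : (r + 1) * rec_bytes]
        if is_bdf:
            raw = np.frombuffer(rec, dtype=np.uint8).reshape(n_ch, spr[0], 3)
            vals = (
                raw[..., 0].astype(np.int32)
                | (raw[..., 1].astype(np.int32) << 8)
                | (raw[..., 2].astype(np.int32) << 16)
            )
            vals = np.where(vals >= 1 << 23, vals - (1 << 24), vals)
        else:
            vals = (
                np.frombuffer(rec, dtype="<i2").reshape(n_ch, spr[0]).astype(np.int32)
            )
        out[:, r * spr[0] : (r + 1) * spr[0]] = vals
    scale = (pmax - pmin) / (dmax - dmin)
    out = (out - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return out, fs, labels


def load_recording(
    path: str | Path,
    epoch_length_s: float = 1.0,
    channels: list[str] | None = None,
) -> dict[str, TrialEnsemble]:
    """Epoch an EDF/BDF recording into per-channel trial ensembles."""
    data, fs, labels = read_recording(path)
    if channels is not None:
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ValueError(f"channels not present in recording: {missing}")
        idx = [labels.index(c) for c in channels]
        data, labels = data[idx], list(channels)
    T = int(round(epoch_length_s * fs))
    if T > data.shape[1]:
        raise ValueError(
            f"epoch of {T} samples longer than record ({data.shape[1]} samples)"
        )
    n_trials = data.shape[1] // T
    return {
        lab: TrialEnsemble(
            data=data[c, : n_trials * T].reshape(n_trials, T), fs=fs, channel_id=lab
        )
        for c, lab in enumerate(labels)
    }


# ---------------------------------------------------------------------------
# HDF5 persistence


def save_tensor(path: str | Path, tensor: PACTensor, config: dict | None = None, seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.create_dataset("values", data=tensor.values)
        fh.create_dataset(
            "channel_labels", data=[str(x) for x in tensor.channel_labels]
        )
        fh.create_dataset("band_labels", data=[str(x) for x in tensor.band_labels])
        fh.create_dataset(
            "subject_labels", data=[str(x) for x in tensor.subject_labels]
        )
        if config is not None:
            fh.attrs["config"] = json.dumps(config)
        if seed is not None:
            fh.attrs["seed"] = int(seed)


def _check_version(fh: h5py.File, path) -> None:
    version = fh.attrs.get("format_version", "<missing>")
    if version != FORMAT_VERSION:
        warnings.warn(
            f"{path}: format version {version!r} != {FORMAT_VERSION!r}; "
            "attempting best-effort read",
            RuntimeWarning,
        )


def load_tensor(path: str | Path) -> tuple[PACTensor, dict]:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        meta = {
            "config": json.loads(fh.attrs["config"]) if "config" in fh.attrs else None,
            "seed": int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
        }
        tensor = PACTensor(
            values=fh["values"][()],
            channel_labels=[x.decode() for x in fh["channel_labels"][()]],
            band_labels=[x.decode() for x in fh["band_labels"][()]],
            subject_labels=[x.decode() for x in fh["subject_labels"][()]],
        )
    return tensor, meta


def save_decomposition(path: str | Path, decomposition, config: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.create_dataset("low_rank", data=decomposition.low_rank)
        fh.create_dataset("sparse", data=decomposition.sparse)
        fh.attrs["lambda"] = decomposition.lam
        fh.attrs["iterations"] = decomposition.iterations
        fh.attrs["primal_residual"] = decomposition.primal_residual
        fh.attrs["converged"] = decomposition.converged
        if config is not None:
            fh.attrs["config"] = json.dumps(config)


def load_decomposition(path: str | Path):
    from .horpca import HoRPCADecomposition

    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        return HoRPCADecomposition(
            low_rank=fh["low_rank"][()],
            sparse=fh["sparse"][()],
            lam=float(fh.attrs["lambda"]),
            iterations=int(fh.attrs["iterations"]),
            primal_residual=float(fh.attrs["primal_residual"]),
            converged=bool(fh.attrs["converged"]),
        )


def write_manifest(path: str | Path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    """Reproducibility manifest: config echo, stage seed, library versions."""
    import scipy

    from . import __version__

    manifest = {
        "stage": stage,
        "rng_seed": config.rng_seed,
        "stage_seed": config.stage_seed(stage),
        "sections": config.sections,
        "versions": {
            "mvpac": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "h5py": h5py.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
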