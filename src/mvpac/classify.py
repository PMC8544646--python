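"""Sparse-representation nearest-neighbour classification of PAC tensors.

Training tensors (one per class) are decomposed by HoRPCA; each test sample
is appended along the subject mode to every class's training tensor, the
decomposition is re-run, and the test sample's sparse slice at a configured
band is compared (Frobenius distance) with every training sparse slice.  The
predicted label is the class of the globally nearest training slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .horpca import default_lambda, horpca_singleton

__all__ = ["LabeledTensorSet", "src_classify", "cross_validate"]

#: default band slice used for classification features (theta-gamma)
DEFAULT_BAND_INDEX = 1


@dataclass
class LabeledTensorSet:
    """Per-class PAC tensors sharing channel and band dimensions."""

    tensors: dict  # label -> ndarray (N, N, M, n_subjects)
    band_index: int = DEFAULT_BAND_INDEX

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape[:3] for k, v in self.tensors.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"class tensors disagree on (N, N, M): {shapes}")


def _sparse_slices(tensor: np.ndarray, band: int, **horpca_kwargs) -> np.ndarray:
    dec = horpca_singleton(tensor, warn=False, **horpca_kwargs)
    return dec.sparse[:, :, band, :]


def src_classify(
    train_tensors: dict,
    test_samples: np.ndarray,
    band_index: int = DEFAULT_BAND_INDEX,
    **horpca_kwargs,
) -> tuple[list, np.ndarray]:
    """Classify test samples against per-class training tensors.

    Parameters
    ----------
    train_tensors:
        Mapping label -> training tensor of shape ``(N, N, M, J)``.
    test_samples:
        Array of shape ``(n_test, N, N, M)``.

    Returns
    -------
    ``(labels, distances)`` where ``distances[t, c]`` is the smallest
    Frobenius distance from test sample ``t`` to any training sparse slice of
    class ``c`` (classes in sorted label order).
    """
    labels_sorted = sorted(train_tensors, key=str)
    shapes = {np.asarray(v).shape[:3] for v in train_tensors.values()}
    if len(shapes) != 1 or np.asarray(test_samples).shape[1:] not in {
        s for s in shapes
    }:
        raise ValueError("test samples and training tensors must share (N, N, M)")
    train_feats = {
        c: _sparse_slices(np.asarray(train_tensors[c]), band_index, **horpca_kwargs)
        for c in labels_sorted
    }
    out_labels = []
    dist_table = np.empty((len(test_samples), len(labels_sorted)))
    for t, sample in enumerate(np.asarray(test_samples)):
        for ci, c in enumerate(labels_sorted):
            train = np.asarray(train_tensors[c])
            aug = np.concatenate([train, sample[..., None]], axis=-1)
            lam = default_lambda(aug.shape)
            feats = _sparse_slices(aug, band_index, lam=lam, **horpca_kwargs)
            test_feat = feats[:, :, -1]
            diffs = train_feats[c] - test_feat[:, :, None]
            dist_table[t, ci] = np.sqrt((diffs**2).sum(axis=(0, 1))).min()
        out_labels.append(labels_sorted[int(np.argmin(dist_table[t]))])
    return out_labels, dist_table


@dataclass
class CVResult:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    g_mean: float
    per_repetition: list = field(default_factory=list)


def cross_validate(
    dataset: LabeledTensorSet,
    n_folds: int = 5,
    n_repetitions: int = 1,
    rng_seed: int | None = 0,
    **horpca_kwargs,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of :func:`src_classify`.

    Binary metrics (precision/recall/F/G-mean) treat the lexicographically
    first class label as the positive class.
    """
    labels_sorted = sorted(dataset.tensors, key=str)
    rng = np.random.default_rng(rng_seed)
    n_per_class = {c: np.asarray(v).shape[-1] for c, v in dataset.tensors.items()}
    if any(n < n_folds for n in n_per_class.values()):
        raise ValueError("need at least n_folds subjects per class")
    reps = []
    for _ in range(n_repetitions):
        folds = {
            c: np.array_split(rng.permutation(n_per_class[c]), n_folds)
            for c in labels_sorted
        }
        y_true, y_pred = [], []
        for f in range(n_folds):
            train = {}
            test_samples, test_labels = [], []
            for c in labels_sorted:
                arr = np.asarray(dataset.tensors[c])
                test_idx = folds[c][f]
                train_idx = np.setdiff1d(np.arange(n_per_class[c]), test_idx)
                train[c] = arr[..., train_idx]
                for i in test_idx:
                    test_samples.append(arr[..., i])
                    test_labels.append(c)
            pred, _ = src_classify(
                train,
                np.asarray(test_samples),
                band_index=dataset.band_index,
                **horpca_kwargs,
            )
            y_true.extend(test_labels)
            y_pred.extend(pred)
        pos = labels_sorted[0]
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == pos and p == pos)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != pos and p == pos)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == pos and p != pos)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t != pos and p != pos)
        acc = (tp + tn) / max(len(y_true), 1)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        reps.append(
            {
                "accuracy": acc,
                "precision": prec,
                "recall": rec,
                "f_measure": f1,
                "g_mean": float(np.sqrt(rec * spec)),
            }
        )
    mean = {k: float(np.mean([r[k] for r in reps])) for k in reps[0]}
    return CVResult(per_repetition=reps, **mean)
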