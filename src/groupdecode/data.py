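"""Epoched multi-subject datasets: containers, preprocessing, splits, HDF5 I/O.

The central container is :class:`EpochedDataset`, holding trials of shape
``(n_trials, n_channels, n_timepoints)`` together with integer class labels,
integer subject ids and sampling metadata.  Preprocessing follows standard
decoding practice: per-channel standardisation for group-level models and
full-rank PCA whitening (per subject) for subject-level models, with the
statistics always estimated on training trials and re-applied to held-out
trials.  Splits are stratified jointly by subject and class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochedDataset",
    "SensorLayout",
    "SplitSpec",
    "load_epochs",
    "save_epochs",
    "standardize_per_channel",
    "whiten_channels",
    "stratified_split",
    "make_kfold",
    "split_to_csv",
]


class FormatError(ValueError):
    """An on-disk file does not conform to the expected HDF5 layout."""


class ValidationError(ValueError):
    """Arrays violate a dataset invariant (shapes, finiteness, balance)."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested transform (e.g. constant channel)."""


@dataclass
class SensorLayout:
    """Channel coordinates plus a partition of channels into co-located groups.

    ``location_group[c]`` is the integer group id of channel ``c``; on MEG
    systems with co-located magnetometer/gradiometer triplets a group is one
    physical sensor location.
    """

    positions: np.ndarray  # (C, 2) or (C, 3)
    location_group: np.ndarray  # (C,) int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.location_group = np.asarray(self.location_group, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValidationError("positions must be (C, 2) or (C, 3)")
        if self.location_group.shape != (self.positions.shape[0],):
            raise ValidationError("location_group must have one entry per channel")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def groups(self) -> list[np.ndarray]:
        """Channel index sets, one per location group, in group-id order."""
        ids = np.unique(self.location_group)
        return [np.flatnonzero(self.location_group == g) for g in ids]

    def neighborhood(self, channel: int, n_neighbors: int = 3) -> np.ndarray:
        """A channel plus its ``n_neighbors`` closest channels by coordinate distance."""
        d = np.linalg.norm(self.positions - self.positions[channel], axis=1)
        order = np.argsort(d, kind="stable")
        return np.sort(order[: n_neighbors + 1])


@dataclass
class EpochedDataset:
    """Epoched trials (n x C x T) with class labels and subject ids.

    ``t0`` is the time of sample 0 relative to stimulus onset in seconds
    (negative = pre-stimulus); sample ``i`` sits at ``t0 + i / fs``.
    """

    trials: np.ndarray  # (n, C, T) float
    labels: np.ndarray  # (n,) int in [0, K)
    subjects: np.ndarray  # (n,) int in [0, s)
    fs: float
    t0: float = 0.0
    balanced: bool = False
    layout: SensorLayout | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.trials.ndim != 3:
            raise ValidationError("trials must be 3-dimensional (n, C, T)")
        n = self.trials.shape[0]
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise ValidationError(
                "labels and subjects must match the first trial dimension"
            )
        if not np.all(np.isfinite(self.trials)):
            raise ValidationError("trials contain non-finite values")
        if n and (self.labels.min() < 0 or self.subjects.min() < 0):
            raise ValidationError("labels and subjects must be non-negative")
        if self.layout is not None and self.layout.n_channels != self.n_channels:
            raise ValidationError("layout channel count does not match trials")
        if self.balanced and n:
            cells = pd.crosstab(self.subjects, self.labels).to_numpy()
            if cells.min() != cells.max():
                raise ValidationError(
                    "dataset declared balanced but (subject, class) counts differ"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.trials.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_trials else 0

    @property
    def n_subjects(self) -> int:
        return int(self.subjects.max()) + 1 if self.n_trials else 0

    @property
    def times(self) -> np.ndarray:
        """Time of each sample relative to stimulus onset, in seconds."""
        return self.t0 + np.arange(self.n_timepoints) / self.fs

    def time_to_sample(self, t: float) -> int:
        """Convert a time in seconds to the nearest sample index (round(x*fs))."""
        return int(round((t - self.t0) * self.fs))

    def subject_indices(self, subject: int) -> np.ndarray:
        return np.flatnonzero(self.subjects == subject)

    def select(self, indices: np.ndarray) -> "EpochedDataset":
        """Row subset; the result is not declared balanced."""
        idx = np.asarray(indices)
        return replace(
            self,
            trials=self.trials[idx],
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            balanced=False,
        )


@dataclass
class SplitSpec:
    """Disjoint train/validation index sets, stratified per (subject, class)."""

    train_indices: np.ndarray
    val_indices: np.ndarray
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=np.int64)
        self.val_indices = np.asarray(self.val_indices, dtype=np.int64)
        if np.intersect1d(self.train_indices, self.val_indices).size:
            raise ValidationError("train and validation indices overlap")


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_epochs(dataset: EpochedDataset, path, overwrite: bool = False) -> None:
    """Write a dataset to the HDF5 layout (float32 trials, int64 labels/subjects)."""
    import os

    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=dataset.trials.astype(np.float32))
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("subjects", data=dataset.subjects)
        f.attrs["fs"] = float(dataset.fs)
        f.attrs["t0"] = float(dataset.t0)
        f.attrs["balanced"] = bool(dataset.balanced)
        if dataset.layout is not None:
            g = f.create_group("layout")
            g.create_dataset("positions", data=dataset.layout.positions)
            g.create_dataset("location_group", data=dataset.layout.location_group)


def load_epochs(path) -> EpochedDataset:
    """Read a dataset written by :func:`save_epochs`, validating all invariants."""
    with h5py.File(path, "r") as f:
        for name in ("trials", "labels", "subjects"):
            if name not in f:
                raise FormatError(f"missing dataset /{name} in {path}")
        for attr in ("fs", "t0"):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute {attr!r} in {path}")
        layout = None
        if "layout" in f:
            layout = SensorLayout(
                positions=f["layout/positions"][()],
                location_group=f["layout/location_group"][()],
            )
        return EpochedDataset(
            trials=f["trials"][()],
            labels=f["labels"][()],
            subjects=f["subjects"][()],
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs["t0"]),
            balanced=bool(f.attrs.get("balanced", False)),
            layout=layout,
        )


def from_mne_epochs(epochs, subjects) -> EpochedDataset:
    """Adapter from an MNE Epochs object (optional; requires mne at call time)."""
    data = epochs.get_data(copy=True)
    labels = epochs.events[:, 2]
    # remap event codes to a contiguous 0..K-1 range
    _, labels = np.unique(labels, return_inverse=True)
    return EpochedDataset(
        trials=data,
        labels=labels,
        subjects=np.asarray(subjects, dtype=np.int64),
        fs=float(epochs.info["sfreq"]),
        t0=float(epochs.times[0]),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ChannelScaler:
    """Per-channel affine standardisation statistics (population variance)."""

    mean: np.ndarray  # (C,)
    var: np.ndarray  # (C,)

    def apply(self, trials: np.ndarray) -> np.ndarray:
        return (trials - self.mean[:, None]) / np.sqrt(self.var)[:, None]


def standardize_per_channel(
    dataset: EpochedDataset, fit_indices: np.ndarray | None = None
) -> tuple[EpochedDataset, ChannelScaler]:
    """Standardise each channel to zero mean / unit variance over the fit trials.

    Statistics are pooled over (fit trials x time) per channel and the same
    affine transform is applied to every trial, so held-out trials see the
    training statistics only.
    """
    if fit_indices is None:
        fit_indices = np.arange(dataset.n_trials)
    fit = dataset.trials[np.asarray(fit_indices)]
    mean = fit.mean(axis=(0, 2))
    var = fit.var(axis=(0, 2))  # population variance (divide by N)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise DegenerateInputError(
            f"zero-variance channel(s) {bad.tolist()} over fit trials"
        )
    scaler = ChannelScaler(mean=mean, var=var)
    out = replace(dataset, trials=scaler.apply(dataset.trials))
    return out, scaler


@dataclass
class WhiteningTransform:
    """Full-rank PCA whitening over channels: y = P (x - mean)."""

    mean: np.ndarray  # (C,)
    projection: np.ndarray  # (C, C)
    rank_deficient: bool = False

    def apply(self, trials: np.ndarray) -> np.ndarray:
        centered = trials - self.mean[:, None]
        return np.einsum("dc,nct->ndt", self.projection, centered)


def whiten_channels(
    dataset: EpochedDataset,
    fit_indices: np.ndarray | None = None,
    rcond: float = 1e-12,
) -> tuple[EpochedDataset, WhiteningTransform]:
    """PCA-whiten the channel dimension, keeping all C components.

    The channel covariance is estimated over (fit trials x time); the stored
    projection maps any trial into the space where the fit-data channel
    covariance is the identity.  Rank-deficient covariances fall back to a
    pseudo-inverse (eigenvalues below ``rcond * max`` are dropped from the
    inverse scaling) with a warning.
    """
    if fit_indices is None:
        fit_indices = np.arange(dataset.n_trials)
    fit = dataset.trials[np.asarray(fit_indices)]
    C = dataset.n_channels
    samples = fit.transpose(1, 0, 2).reshape(C, -1)  # channels x observations
    if samples.shape[1] < C:
        raise DegenerateInputError(
            f"need at least {C} samples to estimate a {C}x{C} covariance"
        )
    mean = samples.mean(axis=1)
    centered = samples - mean[:, None]
    cov = centered @ centered.T / centered.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    rank_deficient = bool(evals.min() <= rcond * evals.max())
    if rank_deficient:
        warnings.warn(
            "rank-deficient channel covariance; whitening uses a pseudo-inverse",
            RuntimeWarning,
        )
    inv_scale = np.where(evals > rcond * evals.max(), 1.0 / np.sqrt(np.maximum(evals, 0)), 0.0)
    projection = (evecs * inv_scale) @ evecs.T  # symmetric (ZCA-style) whitener, C comps
    transform = WhiteningTransform(mean=mean, projection=projection, rank_deficient=rank_deficient)
    out = replace(dataset, trials=transform.apply(dataset.trials))
    return out, transform


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _cell_indices(dataset: EpochedDataset):
    """Iterate (subject, class) cells as index arrays, in sorted order."""
    for s in np.unique(dataset.subjects):
        for k in np.unique(dataset.labels):
            idx = np.flatnonzero((dataset.subjects == s) & (dataset.labels == k))
            if idx.size:
                yield (int(s), int(k)), idx


def stratified_split(
    dataset: EpochedDataset, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> SplitSpec:
    """Train/validation split stratified per subject AND per class.

    ``ratio=(4, 1)`` puts 1/5 of each (subject, class) cell in validation.
    When the cell size is not divisible, validation gets the floor and train
    the remainder.
    """
    tr, va = ratio
    if tr < 0 or va < 0 or tr + va == 0:
        raise ValueError("ratio parts must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for (s, k), idx in _cell_indices(dataset):
        if idx.size < 2:
            raise ValidationError(
                f"subject {s}, class {k} has {idx.size} trial(s); need >= 2"
            )
        n_val = int(np.floor(idx.size * va / (tr + va)))
        perm = rng.permutation(idx)
        val.append(perm[:n_val])
        train.append(perm[n_val:])
    return SplitSpec(
        train_indices=np.sort(np.concatenate(train)),
        val_indices=np.sort(np.concatenate(val)) if val else np.empty(0, np.int64),
        ratio=ratio,
        seed=seed,
    )


def make_kfold(dataset: EpochedDataset, k: int, seed: int = 0) -> list[SplitSpec]:
    """k stratified folds; each trial is in exactly one fold's validation set."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_val: list[list[np.ndarray]] = [[] for _ in range(k)]
    for (s, kl), idx in _cell_indices(dataset):
        if idx.size < k:
            raise ValidationError(
                f"subject {s}, class {kl} has {idx.size} trials < k={k}"
            )
        perm = rng.permutation(idx)
        for i, chunk in enumerate(np.array_split(perm, k)):
            fold_val[i].append(chunk)
    all_idx = np.arange(dataset.n_trials)
    specs = []
    for i in range(k):
        val = np.sort(np.concatenate(fold_val[i]))
        train = np.setdiff1d(all_idx, val)
        specs.append(SplitSpec(train_indices=train, val_indices=val, ratio=(k - 1, 1), seed=seed))
    return specs


def split_to_csv(spec: SplitSpec, dataset: EpochedDataset, path) -> None:
    """Export split membership as CSV (trial_index, role, subject, class)."""
    rows = []
    for role, idx in (("train", spec.train_indices), ("val", spec.val_indices)):
        for i in idx:
            rows.append((int(i), role, int(dataset.subjects[i]), int(dataset.labels[i])))
    pd.DataFrame(rows, columns=["trial_index", "role", "subject", "class"]).to_csv(
        path, index=False
    )
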