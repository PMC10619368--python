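"""Permutation feature importance (PFI) and kernel frequency analysis.

PFI measures how much held-out accuracy drops when a restricted region of the
input — a time window, a channel group, a frequency band, or a
(channel-neighborhood x time-window) patch — is disrupted by permuting the
values inside it.  All perturbations are measure-preserving: they permute
existing values (or Fourier coefficients), so the perturbed region keeps its
value multiset (or band power) and everything outside is left bit-identical.

The same perturbations can be scored at the level of a single convolutional
kernel, where the importance measure is the mean absolute deviation of the
kernel's post-activation output between original and perturbed inputs.
Kernel FIR analysis characterises a kernel's frequency response directly by
feeding white noise through the conv stack and estimating the output power
spectral density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .data import EpochedDataset, SensorLayout
from .model import WaveNetClassifier

__all__ = [
    "PerturbationSpec",
    "PFIResult",
    "KernelImportance",
    "KernelSpectrum",
    "apply_perturbation",
    "permute_channels_in_window",
    "permute_time_in_channels",
    "permute_frequency_band",
    "temporal_pfi",
    "spatial_pfi",
    "spatiotemporal_pfi",
    "spectral_pfi",
    "kernel_pfi",
    "kernel_fir",
]


@dataclass
class PerturbationSpec:
    """What to disrupt and how often to repeat the permutation.

    ``window_seconds`` is the temporal window width for temporal and
    spatiotemporal scans; ``channels`` the channel set for a channel-group
    perturbation; ``band_hz`` the (low, high) band for a spectral
    perturbation.
    """

    axis: str  # temporal_window | channel_group | frequency_band | spatiotemporal
    window_seconds: float = 0.1
    channels: np.ndarray | None = None
    band_hz: tuple[float, float] | None = None
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        valid = ("temporal_window", "channel_group", "frequency_band", "spatiotemporal")
        if self.axis not in valid:
            raise ValueError(f"axis must be one of {valid}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class PFIResult:
    """Importance (base accuracy minus permuted accuracy) along a scanned axis."""

    axis: str
    axis_values: np.ndarray  # centers: seconds, channel/group ids, or Hz
    importance: np.ndarray  # (n_points,) or (n_channels, n_points)
    repeats: np.ndarray  # (..., n_repeats) per-repeat permuted metric
    base_accuracy: float

    def ci95(self) -> np.ndarray:
        """Normal-approximation 95% half-width of the repeat dispersion."""
        n = self.repeats.shape[-1]
        return 1.96 * self.repeats.std(axis=-1, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        if self.importance.ndim != 1:
            raise ValueError("to_frame supports 1-D scans only")
        df = pd.DataFrame({"axis_value": self.axis_values,
                           "importance": self.importance})
        for r in range(self.repeats.shape[-1]):
            df[f"repeat_{r}"] = self.repeats[:, r]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class KernelImportance:
    """Output deviation of one kernel along a scanned axis, raw and z-scored."""

    layer: int
    kernel: int
    axis: str
    axis_values: np.ndarray
    deviation: np.ndarray  # mean |original - permuted| per scan point, >= 0
    repeats: np.ndarray

    @property
    def standardized(self) -> np.ndarray:
        sd = self.deviation.std(ddof=0)
        return (self.deviation - self.deviation.mean()) / (sd if sd > 0 else 1.0)


@dataclass
class KernelSpectrum:
    """PSD of a kernel's output under standard-Gaussian noise input."""

    layer: int
    kernel: int
    freqs: np.ndarray  # Hz, within [0, fs/2]
    psd: np.ndarray
    normalized: bool = False

    def normalize(self) -> "KernelSpectrum":
        return KernelSpectrum(self.layer, self.kernel, self.freqs,
                              self.psd / self.psd.sum(), normalized=True)


# ---------------------------------------------------------------------------
# Perturbation primitives
# ---------------------------------------------------------------------------

def permute_channels_in_window(trials: np.ndarray, start: int, stop: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Shuffle channels inside a [start, stop) time window.

    One channel permutation is drawn per trial and applied to all timepoints
    of the window, destroying the spatial pattern while preserving each
    channel's temporal smoothness inside the window.  Data outside the window
    is untouched.
    """
    out = trials.copy()
    C = trials.shape[1]
    for i in range(trials.shape[0]):
        perm = rng.permutation(C)
        out[i, :, start:stop] = trials[i, perm, start:stop]
    return out


def permute_time_in_channels(trials: np.ndarray, channels: np.ndarray,
                             rng: np.random.Generator,
                             window: tuple[int, int] | None = None) -> np.ndarray:
    """Shuffle timepoints independently within each listed channel.

    ``window`` restricts the shuffling to a [start, stop) sample range (used
    by the spatiotemporal scan); by default the whole epoch is permuted.
    """
    out = trials.copy()
    start, stop = window if window is not None else (0, trials.shape[2])
    n = stop - start
    for i in range(trials.shape[0]):
        for c in np.atleast_1d(channels):
            perm = rng.permutation(n)
            out[i, c, start:stop] = trials[i, c, start:stop][perm]
    return out


def permute_frequency_band(trials: np.ndarray, fs: float, low: float, high: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Permute Fourier coefficients inside [low, high) Hz, per channel.

    The rFFT coefficients whose frequencies fall in the band (excluding the
    DC and Nyquist bins, which must stay real) are permuted as complex values
    (real and imaginary parts move together), independently for every channel
    of every trial, and the signal is rebuilt by the inverse transform.
    Conjugate symmetry is automatic with the real FFT, so the reconstruction
    is exactly real-valued.
    """
    T = trials.shape[2]
    if high > fs / 2 + 1e-9:
        raise ValueError(f"band upper edge {high} Hz above Nyquist {fs / 2} Hz")
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    band = np.flatnonzero((freqs >= low) & (freqs < high))
    last_real_bin = len(freqs) - 1 if T % 2 == 0 else len(freqs)  # Nyquist is real for even T
    band = band[(band > 0) & (band < last_real_bin)]
    if band.size <= 1:
        return trials.copy()
    spec = np.fft.rfft(trials, axis=2)
    for i in range(trials.shape[0]):
        for c in range(trials.shape[1]):
            perm = rng.permutation(band.size)
            spec[i, c, band] = spec[i, c, band[perm]]
    return np.fft.irfft(spec, n=T, axis=2)


def apply_perturbation(trials: np.ndarray, spec: PerturbationSpec,
                       rng: np.random.Generator, fs: float | None = None,
                       window: tuple[int, int] | None = None) -> np.ndarray:
    """Dispatch a single perturbation draw according to ``spec.axis``."""
    if spec.axis == "temporal_window":
        if window is None:
            raise ValueError("temporal_window perturbation needs a sample window")
        return permute_channels_in_window(trials, window[0], window[1], rng)
    if spec.axis == "channel_group":
        if spec.channels is None:
            raise ValueError("channel_group perturbation needs spec.channels")
        return permute_time_in_channels(trials, spec.channels, rng)
    if spec.axis == "spatiotemporal":
        if spec.channels is None or window is None:
            raise ValueError("spatiotemporal perturbation needs channels and window")
        return permute_time_in_channels(trials, spec.channels, rng, window=window)
    if spec.axis == "frequency_band":
        if spec.band_hz is None or fs is None:
            raise ValueError("frequency_band perturbation needs band_hz and fs")
        return permute_frequency_band(trials, fs, *spec.band_hz, rng)
    raise AssertionError(spec.axis)


# ---------------------------------------------------------------------------
# Model-level PFI
# ---------------------------------------------------------------------------

def _accuracy(model: WaveNetClassifier, trials, subjects, labels) -> float:
    logits = []
    for i in range(0, trials.shape[0], 512):
        sub = None if subjects is None else subjects[i : i + 512]
        logits.append(model.forward(trials[i : i + 512], sub, train=False))
    return float((np.concatenate(logits).argmax(axis=1) == labels).mean())


def _window_bounds(center: int, width: int, T: int) -> tuple[int, int]:
    """Sample window of `width` centered at `center`, truncated at the edges."""
    lo = max(0, center - width // 2)
    hi = min(T, lo + width)
    lo = max(0, hi - width)
    return lo, hi


def temporal_pfi(model: WaveNetClassifier, dataset: EpochedDataset,
                 indices: np.ndarray, spec: PerturbationSpec,
                 step: int = 1) -> PFIResult:
    """Accuracy-loss timecourse: shuffle channels in a sliding time window.

    For every scanned timestep a window of ``spec.window_seconds`` is centered
    there (truncated at epoch edges), channels are shuffled inside it, and
    the held-out accuracy drop (base minus permuted, averaged over
    ``spec.n_repeats`` draws) is recorded.
    """
    idx = np.asarray(indices)
    trials = dataset.trials[idx]
    subjects = dataset.subjects[idx]
    labels = dataset.labels[idx]
    T = dataset.n_timepoints
    width = max(1, int(round(spec.window_seconds * dataset.fs)))
    rng = np.random.default_rng(spec.seed)
    base = _accuracy(model, trials, subjects, labels)
    centers = np.arange(0, T, step)
    repeats = np.empty((centers.size, spec.n_repeats))
    for ci, center in enumerate(centers):
        lo, hi = _window_bounds(center, width, T)
        for r in range(spec.n_repeats):
            pert = permute_channels_in_window(trials, lo, hi, rng)
            repeats[ci, r] = _accuracy(model, pert, subjects, labels)
    return PFIResult(
        axis="time",
        axis_values=dataset.t0 + centers / dataset.fs,
        importance=base - repeats.mean(axis=1),
        repeats=repeats,
        base_accuracy=base,
    )


def spatial_pfi(model: WaveNetClassifier, dataset: EpochedDataset,
                indices: np.ndarray, groups: list[np.ndarray],
                spec: PerturbationSpec) -> PFIResult:
    """Accuracy loss per channel group when its timecourses are shuffled."""
    idx = np.asarray(indices)
    trials = dataset.trials[idx]
    subjects = dataset.subjects[idx]
    labels = dataset.labels[idx]
    for g in groups:
        if np.atleast_1d(g).size == 0:
            raise ValueError("empty channel group")
    rng = np.random.default_rng(spec.seed)
    base = _accuracy(model, trials, subjects, labels)
    repeats = np.empty((len(groups), spec.n_repeats))
    for gi, g in enumerate(groups):
        for r in range(spec.n_repeats):
            pert = permute_time_in_channels(trials, np.atleast_1d(g), rng)
            repeats[gi, r] = _accuracy(model, pert, subjects, labels)
    return PFIResult(
        axis="channel_group",
        axis_values=np.arange(len(groups)),
        importance=base - repeats.mean(axis=1),
        repeats=repeats,
        base_accuracy=base,
    )


def spatiotemporal_pfi(model: WaveNetClassifier, dataset: EpochedDataset,
                       indices: np.ndarray, spec: PerturbationSpec,
                       n_neighbors: int = 3, time_step: int = 1,
                       channels: np.ndarray | None = None) -> PFIResult:
    """Channel x time importance map from windowed neighborhood shuffling.

    For each channel, the shuffled set is the channel plus its ``n_neighbors``
    closest channels by layout distance; timepoints are shuffled within a
    ``spec.window_seconds`` window slid over the epoch.
    """
    if dataset.layout is None:
        raise ValueError("spatiotemporal PFI needs a sensor layout with positions")
    idx = np.asarray(indices)
    trials = dataset.trials[idx]
    subjects = dataset.subjects[idx]
    labels = dataset.labels[idx]
    T = dataset.n_timepoints
    width = max(1, int(round(spec.window_seconds * dataset.fs)))
    chans = np.arange(dataset.n_channels) if channels is None else np.asarray(channels)
    centers = np.arange(0, T, time_step)
    rng = np.random.default_rng(spec.seed)
    base = _accuracy(model, trials, subjects, labels)
    repeats = np.empty((chans.size, centers.size, spec.n_repeats))
    for ki, ch in enumerate(chans):
        hood = dataset.layout.neighborhood(int(ch), n_neighbors)
        for ci, center in enumerate(centers):
            lo, hi = _window_bounds(center, width, T)
            for r in range(spec.n_repeats):
                pert = permute_time_in_channels(trials, hood, rng, window=(lo, hi))
                repeats[ki, ci, r] = _accuracy(model, pert, subjects, labels)
    return PFIResult(
        axis="channel_time",
        axis_values=dataset.t0 + centers / dataset.fs,
        importance=base - repeats.mean(axis=2),
        repeats=repeats,
        base_accuracy=base,
    )


def _band_centers(bandwidth_hz: float, step_hz: float, fs: float, T: int) -> np.ndarray:
    resolution = fs / T
    if bandwidth_hz < resolution:
        raise ValueError(
            f"bandwidth {bandwidth_hz} Hz below frequency resolution {resolution:.3f} Hz"
        )
    lo = bandwidth_hz / 2
    hi = fs / 2 - bandwidth_hz / 2
    return np.arange(lo, hi + 1e-9, step_hz)


def spectral_pfi(model: WaveNetClassifier, dataset: EpochedDataset,
                 indices: np.ndarray, bandwidth_hz: float, step_hz: float,
                 spec: PerturbationSpec, layer: int | None = None,
                 kernel: int | None = None) -> PFIResult:
    """Accuracy loss (or kernel output deviation) per frequency band.

    Bands of ``bandwidth_hz`` slide by ``step_hz`` across (0, Nyquist);
    within each band the Fourier coefficients of all channels are permuted
    and the trials rebuilt by the inverse transform.  With ``layer``/
    ``kernel`` given, the metric becomes the mean absolute deviation of that
    kernel's output (importance = deviation, base_accuracy is the unperturbed
    model accuracy for reference).
    """
    idx = np.asarray(indices)
    trials = dataset.trials[idx]
    subjects = dataset.subjects[idx]
    labels = dataset.labels[idx]
    centers = _band_centers(bandwidth_hz, step_hz, dataset.fs, dataset.n_timepoints)
    rng = np.random.default_rng(spec.seed)
    base = _accuracy(model, trials, subjects, labels)
    kernel_mode = layer is not None
    if kernel_mode:
        base_out = model.kernel_output(trials, subjects, layer, kernel)
    repeats = np.empty((centers.size, spec.n_repeats))
    for bi, c in enumerate(centers):
        low, high = c - bandwidth_hz / 2, c + bandwidth_hz / 2
        for r in range(spec.n_repeats):
            pert = permute_frequency_band(trials, dataset.fs, low, high, rng)
            if kernel_mode:
                out = model.kernel_output(pert, subjects, layer, kernel)
                repeats[bi, r] = float(np.abs(out - base_out).mean())
            else:
                repeats[bi, r] = _accuracy(model, pert, subjects, labels)
    importance = repeats.mean(axis=1) if kernel_mode else base - repeats.mean(axis=1)
    return PFIResult(
        axis="frequency",
        axis_values=centers,
        importance=importance,
        repeats=repeats,
        base_accuracy=base,
    )


# ---------------------------------------------------------------------------
# Kernel-level analyses
# ---------------------------------------------------------------------------

def kernel_pfi(model: WaveNetClassifier, layer: int, kernel: int,
               dataset: EpochedDataset, indices: np.ndarray,
               spec: PerturbationSpec, step: int = 1,
               groups: list[np.ndarray] | None = None) -> KernelImportance:
    """Perturbation importance scored at a single kernel's output.

    The deviation at each scan point is the mean over trials and output
    timepoints of ``|kernel_output(original) - kernel_output(permuted)|``.
    The scan axis follows ``spec.axis``: a sliding time window
    (``temporal_window``) or channel groups (``channel_group``, defaulting to
    the layout's location groups).
    """
    idx = np.asarray(indices)
    trials = dataset.trials[idx]
    subjects = dataset.subjects[idx]
    base_out = model.kernel_output(trials, subjects, layer, kernel)
    rng = np.random.default_rng(spec.seed)
    T = dataset.n_timepoints

    if spec.axis == "temporal_window":
        width = max(1, int(round(spec.window_seconds * dataset.fs)))
        centers = np.arange(0, T, step)
        repeats = np.empty((centers.size, spec.n_repeats))
        for ci, center in enumerate(centers):
            lo, hi = _window_bounds(center, width, T)
            for r in range(spec.n_repeats):
                pert = permute_channels_in_window(trials, lo, hi, rng)
                out = model.kernel_output(pert, subjects, layer, kernel)
                repeats[ci, r] = float(np.abs(out - base_out).mean())
        axis_values = dataset.t0 + centers / dataset.fs
    elif spec.axis == "channel_group":
        if groups is None:
            if dataset.layout is None:
                raise ValueError("channel_group kernel PFI needs groups or a layout")
            groups = dataset.layout.groups()
        repeats = np.empty((len(groups), spec.n_repeats))
        for gi, g in enumerate(groups):
            for r in range(spec.n_repeats):
                pert = permute_time_in_channels(trials, np.atleast_1d(g), rng)
                out = model.kernel_output(pert, subjects, layer, kernel)
                repeats[gi, r] = float(np.abs(out - base_out).mean())
        axis_values = np.arange(len(groups))
    else:
        raise ValueError(
            "kernel_pfi scans temporal_window or channel_group; use spectral_pfi "
            "with layer/kernel for frequency bands"
        )
    return KernelImportance(
        layer=layer, kernel=kernel, axis=spec.axis, axis_values=axis_values,
        deviation=repeats.mean(axis=1), repeats=repeats,
    )


def kernel_fir(model: WaveNetClassifier, layer: int, kernel: int,
               n_noise_trials: int = 200, seed: int = 0,
               input_length: int = 1024, fs: float | None = None,
               nperseg: int = 128) -> KernelSpectrum:
    """Frequency response of a kernel from its output PSD under white noise.

    Standard-Gaussian noise trials (spanning all conv-block input rows,
    including any embedding rows) are passed through the conv stack; the
    Welch PSD of the selected kernel's output is averaged over trials.  For a
    white input the output PSD is proportional to the kernel path's |H(f)|^2.
    """
    if n_noise_trials < 1:
        raise ValueError("n_noise_trials must be >= 1")
    if fs is None:
        fs = 2.0  # frequency axis in cycles/sample-pair; Nyquist = 1
    rng = np.random.default_rng(seed)
    cfg = model.config
    psd_sum = None
    batch = max(1, min(n_noise_trials, 64))
    done = 0
    while done < n_noise_trials:
        b = min(batch, n_noise_trials - done)
        noise = rng.standard_normal((b, cfg.in_channels, input_length))
        out = model.conv_activations(noise, layer)[:, kernel, :]
        freqs, psd = scipy.signal.welch(out, fs=fs, nperseg=min(nperseg, input_length),
                                        axis=-1)
        s = psd.sum(axis=0)
        psd_sum = s if psd_sum is None else psd_sum + s
        done += b
    return KernelSpectrum(layer=layer, kernel=kernel, freqs=freqs,
                          psd=psd_sum / n_noise_trials)


def plot_sensor_map(layout: SensorLayout, values: np.ndarray, ax=None, **scatter_kw):
    """Scatter channel positions colored by an importance value per channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = layout.positions
    sc = ax.scatter(pts[:, 0], pts[:, 1], c=values, cmap="Reds", **scatter_kw)
    ax.set_aspect("equal")
    return sc
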