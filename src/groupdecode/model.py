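"""Dilated-convolution classifier for epoched trials, with subject embeddings.

The network has two parts.  A stack of ``L`` causal dilated 1-D convolutional
layers (dilation multiplied by ``dilation_base`` each layer, length-preserving
padding, inverse-hyperbolic-sine activation, dropout) acts as a temporal
feature extractor whose receptive field is ``dilation_base ** L``.  Its output
is temporally downsampled by the receptive field, flattened, and passed
through a fully-connected block (hidden layer + activation + dropout, then a
linear map to K class logits).  Setting the activation to the identity makes
the whole network affine in its input — the "linear" model variant.

A learnable per-subject embedding vector may be concatenated to the channel
dimension of every trial (repeated across time), letting a single shared
group model condition its computation on subject identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn

__all__ = [
    "WaveNetConfig",
    "WaveNetClassifier",
    "receptive_field",
    "concat_subject_embedding",
    "temporal_downsample",
    "build_model",
    "set_activation",
    "save_checkpoint",
    "load_checkpoint",
]

ACTIVATIONS = ("asinh", "identity")


def receptive_field(n_conv_layers: int, dilation_base: int = 2) -> int:
    """Receptive field of the dilated conv block: dilation_base ** n_layers.

    With kernel size 2 and the dilation doubling each layer, the block "sees"
    exactly this many input samples per output sample.
    """
    if n_conv_layers < 0:
        raise ValueError("n_conv_layers must be >= 0")
    if dilation_base < 1:
        raise ValueError("dilation_base must be >= 1")
    return dilation_base ** n_conv_layers


@dataclass
class WaveNetConfig:
    """Architecture hyperparameters.

    ``embedding_size == 0`` disables subject embeddings (subject-level and
    naive group models); ``E > 0`` adds an ``n_subjects x E`` learnable table
    whose rows are concatenated to the input channels.
    """

    n_channels: int
    n_timepoints: int
    n_classes: int
    n_conv_layers: int = 6
    kernel_size: int = 2
    hidden_channels: int | None = None  # default: n_channels + embedding_size
    dilation_base: int = 2
    activation: str = "asinh"
    dropout: float = 0.0
    fc_hidden: int = 512
    embedding_size: int = 0
    n_subjects: int = 1
    downsample: str = "last"  # "last" or "mean" within each rf-block

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.embedding_size < 0:
            raise ValueError("embedding_size must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        rf = receptive_field(self.n_conv_layers, self.dilation_base)
        if rf > self.n_timepoints:
            raise ValueError(
                f"receptive field {rf} exceeds trial length {self.n_timepoints}"
            )

    @property
    def in_channels(self) -> int:
        return self.n_channels + self.embedding_size

    @property
    def hidden(self) -> int:
        return self.hidden_channels if self.hidden_channels is not None else self.in_channels

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.n_conv_layers, self.dilation_base)

    @property
    def flat_features(self) -> int:
        return self.hidden_out * (self.n_timepoints // self.receptive_field)

    @property
    def hidden_out(self) -> int:
        """Channel count at the conv-block output (input channels when L=0)."""
        return self.hidden if self.n_conv_layers > 0 else self.in_channels

    def param_count(self) -> int:
        """Closed-form learnable parameter count for this configuration."""
        n = self.n_subjects * self.embedding_size
        cin = self.in_channels
        for _ in range(self.n_conv_layers):
            n += self.hidden * cin * self.kernel_size + self.hidden
            cin = self.hidden
        n += self.fc_hidden * self.flat_features + self.fc_hidden
        n += self.n_classes * self.fc_hidden + self.n_classes
        return n


def set_activation(config: WaveNetConfig, kind: str) -> WaveNetConfig:
    """Return a config with every activation site (conv + fc) set to ``kind``."""
    if kind not in ACTIVATIONS:
        raise ValueError(f"unknown activation {kind!r}")
    return replace(config, activation=kind)


def concat_subject_embedding(trial: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Stack an embedding vector under the channel dimension, tiled over time.

    ``trial`` is (C, T) and ``embedding`` is (E,); the result is (C+E, T) with
    row ``C+j`` constant at ``embedding[j]``.  E=0 returns the trial itself.
    """
    trial = np.asarray(trial)
    embedding = np.asarray(embedding)
    if embedding.size == 0:
        return trial
    if not (np.all(np.isfinite(trial)) and np.all(np.isfinite(embedding))):
        raise ValueError("non-finite input")
    tiled = np.repeat(embedding[:, None], trial.shape[1], axis=1)
    return np.concatenate([trial, tiled], axis=0)


def temporal_downsample(features: np.ndarray, rf: int, how: str = "last") -> np.ndarray:
    """Reduce the time axis by a factor ``rf`` over non-overlapping blocks.

    ``how="last"`` keeps the last sample of each block (whose causal receptive
    field covers the whole block); ``how="mean"`` averages each block.  A tail
    shorter than ``rf`` is truncated.
    """
    if rf <= 0:
        raise ValueError("rf must be positive")
    T = features.shape[-1]
    n_blocks = T // rf
    trimmed = features[..., : n_blocks * rf]
    blocks = trimmed.reshape(*features.shape[:-1], n_blocks, rf)
    if how == "last":
        return blocks[..., -1]
    if how == "mean":
        return blocks.mean(axis=-1)
    raise ValueError(f"unknown downsample rule {how!r}")


class WaveNetClassifier:
    """A built model: config + parameter arrays + explicit forward/backward.

    Parameters live in ``self.params`` (name -> array) so optimisers,
    checkpointing and finetuning can treat them uniformly.  ``forward`` in
    eval mode is deterministic; train mode applies inverted dropout driven by
    the rng passed in.
    """

    def __init__(self, config: WaveNetConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.epoch = 0
        self._cache = None

    # -- construction -----------------------------------------------------
    @classmethod
    def build(cls, config: WaveNetConfig, seed: int = 0) -> "WaveNetClassifier":
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        cin = config.in_channels
        for layer in range(config.n_conv_layers):
            fan_in = cin * config.kernel_size
            params[f"conv{layer}_W"] = rng.normal(
                0.0, 1.0 / np.sqrt(fan_in), (config.hidden, cin, config.kernel_size)
            )
            params[f"conv{layer}_b"] = np.zeros(config.hidden)
            cin = config.hidden
        params["fc1_W"] = rng.normal(
            0.0, 1.0 / np.sqrt(config.flat_features),
            (config.fc_hidden, config.flat_features),
        )
        params["fc1_b"] = np.zeros(config.fc_hidden)
        params["fc2_W"] = rng.normal(
            0.0, 1.0 / np.sqrt(config.fc_hidden), (config.n_classes, config.fc_hidden)
        )
        params["fc2_b"] = np.zeros(config.n_classes)
        if config.embedding_size > 0:
            params["embedding"] = rng.normal(
                0.0, 0.1, (config.n_subjects, config.embedding_size)
            )
        return cls(config, params)

    def copy(self) -> "WaveNetClassifier":
        clone = WaveNetClassifier(self.config, {k: v.copy() for k, v in self.params.items()})
        clone.epoch = self.epoch
        return clone

    def param_count(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- activation helpers -----------------------------------------------
    def _act(self, x):
        return nn.asinh(x) if self.config.activation == "asinh" else x

    def _act_grad(self, x):
        return nn.asinh_grad(x) if self.config.activation == "asinh" else np.ones_like(x)

    # -- forward ----------------------------------------------------------
    def _augment(self, trials: np.ndarray, subjects: np.ndarray | None) -> np.ndarray:
        cfg = self.config
        if cfg.embedding_size == 0:
            return trials
        if subjects is None:
            raise ValueError("subject ids required for a model with embeddings")
        subjects = np.asarray(subjects)
        if subjects.min() < 0 or subjects.max() >= cfg.n_subjects:
            raise ValueError("subject id outside the embedding table range")
        emb = self.params["embedding"][subjects]  # (B, E)
        tiled = np.repeat(emb[:, :, None], trials.shape[2], axis=2)
        return np.concatenate([trials, tiled], axis=1)

    def conv_block(self, x: np.ndarray, train: bool = False,
                   rng: np.random.Generator | None = None,
                   keep_caches: bool = False):
        """Run the dilated conv stack on (B, C+E, T); returns (B, H, T)."""
        cfg = self.config
        caches = []
        h = x
        for layer in range(cfg.n_conv_layers):
            d = cfg.dilation_base ** layer
            pre, xp = nn.dilated_conv1d(
                h, self.params[f"conv{layer}_W"], self.params[f"conv{layer}_b"], d
            )
            h = self._act(pre)
            mask = None
            if train and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                h = h * mask
            if keep_caches:
                caches.append((xp, pre, mask))
        return h, caches

    def conv_activations(self, x: np.ndarray, layer: int) -> np.ndarray:
        """Post-activation output of conv layer ``layer`` for an already
        augmented input (B, C+E, T) of any temporal length (eval mode)."""
        if not 0 <= layer < self.config.n_conv_layers:
            raise IndexError(f"layer {layer} out of range")
        h = np.asarray(x, dtype=float)
        for l in range(layer + 1):
            d = self.config.dilation_base ** l
            pre, _ = nn.dilated_conv1d(
                h, self.params[f"conv{l}_W"], self.params[f"conv{l}_b"], d
            )
            h = self._act(pre)
        return h

    def kernel_output(self, trials: np.ndarray, subjects: np.ndarray | None,
                      layer: int, kernel: int | None = None) -> np.ndarray:
        """Post-activation output of one conv layer (eval mode, no dropout).

        Returns (B, H, T), or (B, T) when ``kernel`` selects one output
        channel.  Used by kernel-level feature-importance analyses.
        """
        x = self._augment(np.asarray(trials, dtype=float), subjects)
        h = self.conv_activations(x, layer)
        if kernel is None:
            return h
        if not 0 <= kernel < h.shape[1]:
            raise IndexError(f"kernel {kernel} out of range")
        return h[:, kernel, :]

    def forward(self, trials: np.ndarray, subjects: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None,
                keep_caches: bool = False) -> np.ndarray:
        """Logits of shape (B, K) for a batch of (B, C, T) trials."""
        cfg = self.config
        if train and cfg.dropout > 0 and rng is None:
            raise ValueError("train-mode forward with dropout needs an rng")
        trials = np.asarray(trials, dtype=float)
        subjects = None if subjects is None else np.asarray(subjects)
        x = self._augment(trials, subjects)
        h, conv_caches = self.conv_block(x, train=train, rng=rng, keep_caches=keep_caches)
        ds = temporal_downsample(h, cfg.receptive_field, cfg.downsample)
        flat = ds.reshape(ds.shape[0], -1)
        pre1 = flat @ self.params["fc1_W"].T + self.params["fc1_b"]
        h1 = self._act(pre1)
        mask1 = None
        if train and cfg.dropout > 0:
            mask1 = (rng.random(h1.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h1 = h1 * mask1
        logits = h1 @ self.params["fc2_W"].T + self.params["fc2_b"]
        if keep_caches:
            self._cache = dict(
                subjects=subjects, conv=conv_caches, h_shape=h.shape,
                flat=flat, pre1=pre1, mask1=mask1, h1=h1,
            )
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits")
        return logits

    # -- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients for every parameter, from the caches of the last forward."""
        cfg = self.config
        c = self._cache
        if c is None:
            raise RuntimeError("forward(..., keep_caches=True) must precede backward")
        grads: dict[str, np.ndarray] = {}
        grads["fc2_W"] = dlogits.T @ c["h1"]
        grads["fc2_b"] = dlogits.sum(axis=0)
        dh1 = dlogits @ self.params["fc2_W"]
        if c["mask1"] is not None:
            dh1 = dh1 * c["mask1"]
        dpre1 = dh1 * self._act_grad(c["pre1"])
        grads["fc1_W"] = dpre1.T @ c["flat"]
        grads["fc1_b"] = dpre1.sum(axis=0)
        dflat = dpre1 @ self.params["fc1_W"]
        B, H, T = c["h_shape"]
        rf = cfg.receptive_field
        n_blocks = T // rf
        dds = dflat.reshape(B, H, n_blocks)
        dh = np.zeros((B, H, T))
        if cfg.downsample == "last":
            dh[:, :, rf - 1 : n_blocks * rf : rf] = dds
        else:  # mean
            dh[:, :, : n_blocks * rf] = np.repeat(dds, rf, axis=2) / rf
        for layer in range(cfg.n_conv_layers - 1, -1, -1):
            xp, pre, mask = c["conv"][layer]
            if mask is not None:
                dh = dh * mask
            dpre = dh * self._act_grad(pre)
            d = cfg.dilation_base ** layer
            dh, dW, db = nn.dilated_conv1d_backward(
                dpre, xp, self.params[f"conv{layer}_W"], d
            )
            grads[f"conv{layer}_W"] = dW
            grads[f"conv{layer}_b"] = db
        if cfg.embedding_size > 0:
            # dh is the gradient w.r.t. the augmented input; embedding rows
            # collect the time-summed gradient of their tiled copies.
            demb_rows = dh[:, cfg.n_channels :, :].sum(axis=2)  # (B, E)
            demb = np.zeros_like(self.params["embedding"])
            np.add.at(demb, c["subjects"], demb_rows)
            grads["embedding"] = demb
        self._cache = None
        return grads


def build_model(config: WaveNetConfig, seed: int = 0) -> WaveNetClassifier:
    """Build a classifier with deterministic seed-driven initialisation."""
    return WaveNetClassifier.build(config, seed)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: WaveNetClassifier, path) -> None:
    """Single-file archive: JSON-encoded config + named parameter arrays."""
    meta = json.dumps({"config": asdict(model.config), "epoch": model.epoch})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path) -> WaveNetClassifier:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        config = WaveNetConfig(**meta["config"])
        params = {k: f[k].copy() for k in f.files if k != "__meta__"}
    model = WaveNetClassifier(config, params)
    model.epoch = meta["epoch"]
    expected = WaveNetClassifier.build(config, seed=0)
    if set(params) != set(expected.params) or any(
        params[k].shape != expected.params[k].shape for k in params
    ):
        raise ValueError("checkpoint parameters inconsistent with its config")
    return model
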