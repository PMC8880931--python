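"""Encoder f(.) and projection head g(.).

The encoder follows a residual 1-D convolutional template: an initial
conv/BN/ReLU/max-pool stem, a chain of residual blocks that downsample
the time axis and widen the channel axis, then global average pooling
over time yielding a fixed-width representation h (default 320). All
convolutions share one kernel width (default 16) and all activations
are ReLU.

The projection head — Dense(320) -> ReLU -> Dense(320), no final
activation — maps h to the projection z used only by the contrastive
loss during pre-training; downstream tasks read h.

The block-internal hyperparameters of the full-size instance (block
count, per-stage channels, per-block downsampling) are a documented
faithful-in-spirit default; every element is configurable, and a
``tiny`` configuration supports desk-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .errors import ArchitectureError


@dataclass(frozen=True)
class EncoderConfig:
    input_length: int = 4096
    n_leads: int = 12
    conv_filter_size: int = 16
    channels_per_stage: tuple = (64, 128, 196, 256, 320)
    representation_dim: int = 320
    downsample_per_block: int = 4
    stem_pool: int = 2

    def __post_init__(self):
        counts = (self.input_length, self.n_leads, self.conv_filter_size,
                  self.representation_dim, self.downsample_per_block,
                  *self.channels_per_stage)
        if any(c < 1 for c in counts):
            raise ArchitectureError("all configuration counts must be >= 1")
        if len(self.channels_per_stage) < 2:
            raise ArchitectureError(
                "channels_per_stage needs a stem entry plus >= 1 block")
        if self.representation_dim != self.channels_per_stage[-1]:
            raise ArchitectureError(
                f"representation_dim {self.representation_dim} != last "
                f"channel count {self.channels_per_stage[-1]}")
        # input length must divide through the stem pool and every block
        L = self.input_length
        for factor in (self.stem_pool,
                       *([self.downsample_per_block] * self.n_residual_blocks)):
            if L % factor:
                raise ArchitectureError(
                    f"input length {self.input_length} is not divisible "
                    f"through the downsampling chain (stuck at {L} / {factor})")
            L //= factor

    @property
    def n_residual_blocks(self) -> int:
        return len(self.channels_per_stage) - 1

    @classmethod
    def tiny(cls, input_length: int = 256) -> "EncoderConfig":
        """Desk-scale instance for tests and examples."""
        return cls(input_length=input_length, conv_filter_size=8,
                   channels_per_stage=(8, 8, 16), representation_dim=16,
                   downsample_per_block=4)


@dataclass(frozen=True)
class ProjectionConfig:
    hidden_units: int = 320
    output_units: int = 320

    def __post_init__(self):
        if self.hidden_units < 1 or self.output_units < 1:
            raise ArchitectureError("projection unit counts must be >= 1")


class Encoder:
    """Parametric map from (batch, length, leads) ECG arrays to
    (batch, representation_dim) representations."""

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 dropout: float = 0.0):
        self.config = config
        self.seed = seed
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        ch = config.channels_per_stage
        layers = [
            _nn.Conv1D(config.n_leads, ch[0], config.conv_filter_size, rng=rng),
            _nn.BatchNorm1D(ch[0]),
            _nn.ReLU(),
            _nn.MaxPool1D(config.stem_pool),
        ]
        for i in range(config.n_residual_blocks):
            layers.append(_nn.ResidualBlock(
                ch[i], ch[i + 1], config.conv_filter_size,
                config.downsample_per_block, dropout=dropout, rng=rng))
        layers.append(_nn.GlobalAveragePool())
        self.net = _nn.Sequential(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.input_length or \
                x.shape[2] != self.config.n_leads:
            raise ArchitectureError(
                f"input shape {x.shape[1:]} incompatible with configured "
                f"({self.config.input_length}, {self.config.n_leads})")
        return self.net.forward(x, training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def encode(self, tensors, batch_size: int = 128) -> np.ndarray:
        """Inference-mode representations for ECGTensors or arrays."""
        arrays = [t.values if hasattr(t, "values") else np.asarray(t)
                  for t in tensors]
        if not arrays:
            return np.zeros((0, self.config.representation_dim))
        X = np.stack(arrays)
        out = [self.forward(X[i:i + batch_size], training=False)
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)

    def params(self):
        return _nn.collect_params(self.net)

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_state(self):
        return _nn.get_state(self.net)

    def set_state(self, state):
        _nn.set_state(self.net, state)

    def describe(self) -> str:
        c = self.config
        L = c.input_length // c.stem_pool
        lines = [
            f"Encoder(input={c.input_length}x{c.n_leads}, "
            f"kernel={c.conv_filter_size})",
            f"  stem: Conv1D({c.n_leads}->{c.channels_per_stage[0]}) "
            f"+ BN + ReLU + MaxPool({c.stem_pool}) -> length {L}",
        ]
        for i in range(c.n_residual_blocks):
            L //= c.downsample_per_block
            lines.append(
                f"  res-block {i + 1}: {c.channels_per_stage[i]}->"
                f"{c.channels_per_stage[i + 1]} /{c.downsample_per_block} "
                f"-> length {L}")
        lines.append(f"  GAP -> h in R^{c.representation_dim}")
        lines.append(f"  parameters: {self.n_params:,}")
        return "\n".join(lines)


class ProjectionHead:
    """Dense -> ReLU -> Dense; used only during pre-training."""

    def __init__(self, config: ProjectionConfig = None, input_dim: int = 320,
                 seed: int = 0):
        self.config = config or ProjectionConfig()
        rng = np.random.default_rng(seed)
        self.net = _nn.Sequential([
            _nn.Dense(input_dim, self.config.hidden_units, rng=rng),
            _nn.ReLU(),
            _nn.Dense(self.config.hidden_units, self.config.output_units,
                      rng=rng),
        ])

    def forward(self, h: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(h, dtype=np.float64),
                                training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def params(self):
        return _nn.collect_params(self.net)

    def get_state(self):
        return _nn.get_state(self.net)

    def set_state(self, state):
        _nn.set_state(self.net, state)


def build_encoder(config: EncoderConfig | None = None, seed: int = 0,
                  dropout: float = 0.0) -> Encoder:
    return Encoder(config or EncoderConfig(), seed=seed, dropout=dropout)


def build_projection_head(config: ProjectionConfig | None = None,
                          input_dim: int = 320, seed: int = 0) -> ProjectionHead:
    return ProjectionHead(config, input_dim=input_dim, seed=seed)


def save_encoder(path: str, encoder: Encoder) -> None:
    """Persist an encoder's config + weights as .npz (+ sidecar json)."""
    arrays = _nn.flatten_state(encoder.get_state())
    meta = {"config": encoder.config.__dict__ | {
        "channels_per_stage": list(encoder.config.channels_per_stage)},
        "seed": encoder.seed, "dropout": encoder.dropout}
    np.savez(path, meta=json.dumps(meta),
             **{f"arr{i}": a for i, a in enumerate(arrays)})


def load_encoder(path: str) -> Encoder:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg_d = dict(meta["config"])
    cfg_d["channels_per_stage"] = tuple(cfg_d["channels_per_stage"])
    enc = Encoder(EncoderConfig(**cfg_d), seed=meta["seed"],
                  dropout=meta["dropout"])
    arrays = [data[f"arr{i}"] for i in range(len(data.files) - 1)]
    state, _ = _nn.unflatten_state(enc.get_state(), arrays)
    enc.set_state(state)
    return enc
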