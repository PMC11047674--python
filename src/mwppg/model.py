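"""The attention CNN + bidirectional-LSTM blood-pressure regressor.

Architecture (per conv block): 2-D convolution → batch normalisation →
SELU (self-normalising activation) → squeeze-and-excitation channel
attention → 2x2 average downsampling.  After the conv stack the feature
map is read as a sequence along its width (time) axis — scalogram columns
are time steps — with height collapsed by average pooling, passed through
a two-layer bidirectional LSTM, and regressed by two dense layers onto
(SBP, DBP) jointly.

Three input variants mirror the experiment structure:

* ``single``      — one wavelength's H x W x 3 scalogram image;
* ``four_branch`` — four weight-independent conv stacks, one per
  wavelength, whose per-step features are concatenated ("spliced") before
  the shared recurrent stage;
* ``fused12``     — the depth-stacked H x W x 12 tensor through a single
  conv stack.

The network's raw outputs live in a standardised target space; training
sets the per-output affine de-standardisation (``output_mean``/
``output_sd``) so that :func:`predict` returns mmHg.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigError, ShapeError

VARIANTS = ("single", "four_branch", "fused12")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults are desk-scale choices).

    The conv stack depth/widths, kernel, attention reduction, LSTM hidden
    size and dense sizes are all open choices; defaults keep the model
    under ~2M parameters so it trains on one CPU.
    """

    variant: str = "fused12"
    conv_blocks: int = 3
    conv_channels: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    attention_reduction: int = 8
    lstm_layers: int = 2
    lstm_hidden: int = 128
    fc_sizes: tuple[int, int] = (64, 2)
    outputs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}; got {self.variant!r}")
        if len(self.conv_channels) != self.conv_blocks:
            raise ConfigError("conv_channels length must equal conv_blocks")
        if self.outputs != 2:
            raise ConfigError("the regressor jointly predicts (SBP, DBP); outputs must be 2")
        if self.lstm_layers != 2:
            raise ConfigError("the recurrent stage is a two-layer Bi-LSTM; lstm_layers must be 2")
        if len(self.fc_sizes) != 2 or self.fc_sizes[-1] != self.outputs:
            raise ConfigError("fc_sizes must be (hidden, 2): two dense layers ending in (SBP, DBP)")

    @property
    def in_channels(self) -> int:
        return 3 if self.variant == "single" else 12

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_channels", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def channel_attention(
    features: np.ndarray, reduction: int = 8, seed: int = 0
) -> np.ndarray:
    """Apply a (freshly initialised, seeded) SE attention block to a map.

    ``features`` is (B, C, H, W); the output has the same shape, each
    channel rescaled by a weight strictly inside (0, 1).  Exposed as the
    stand-alone form of the attention stage for inspection and testing;
    inside the model the block's weights are trained.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 4:
        raise ShapeError("channel_attention expects (B, C, H, W)")
    block = nn.SEAttention(features.shape[1], reduction, np.random.default_rng(seed))
    return block.forward(features, train=False)


class _ConvStack:
    """Cascaded conv blocks: conv → BN → SELU → SE attention → 2x2 pool."""

    def __init__(self, in_ch: int, cfg: ModelConfig, rng: np.random.Generator):
        self.layers: list[nn.Layer] = []
        c = in_ch
        for out_c in cfg.conv_channels:
            self.layers += [
                nn.Conv2d(c, out_c, cfg.kernel, rng),
                nn.BatchNorm2d(out_c),
                nn.SELU(),
                nn.SEAttention(out_c, cfg.attention_reduction, rng),
                nn.AvgPool2(),
            ]
            c = out_c
        self.layers.append(nn.HeightPoolToSequence())
        self.out_dim = c

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ACNNBiLSTM:
    """The full regressor; see module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig, in_channels: int | None = None):
        in_channels = cfg.in_channels if in_channels is None else in_channels
        if in_channels != cfg.in_channels:
            raise ConfigError(
                f"variant {cfg.variant!r} expects {cfg.in_channels}-channel input; "
                f"got in_channels={in_channels}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.variant == "four_branch":
            self.branches = [_ConvStack(3, cfg, rng) for _ in range(4)]
            seq_dim = 4 * self.branches[0].out_dim
        else:
            self.branches = [_ConvStack(in_channels, cfg, rng)]
            seq_dim = self.branches[0].out_dim
        self.lstm = nn.BiLSTM(seq_dim, cfg.lstm_hidden, cfg.lstm_layers, rng)
        self.pool = nn.TemporalMean()
        self.fc1 = nn.Dense(self.lstm.out_dim, cfg.fc_sizes[0], rng)
        self.act = nn.SELU()
        self.fc2 = nn.Dense(cfg.fc_sizes[0], cfg.fc_sizes[1], rng)
        # De-standardisation to mmHg; set by training from the train labels.
        self.output_mean = np.zeros(cfg.outputs)
        self.output_sd = np.ones(cfg.outputs)

    # -- parameters -------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for b in self.branches:
            out.extend(b.params())
        out.extend(self.lstm.params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward (standardised target space) -------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[3] != self.cfg.in_channels:
            raise ShapeError(
                f"expected input (B, H, W, {self.cfg.in_channels}) for variant "
                f"{self.cfg.variant!r}; got {x.shape}"
            )
        stride = 2 ** self.cfg.conv_blocks
        if x.shape[1] % stride or x.shape[2] % stride:
            raise ShapeError(
                f"image size {x.shape[1:3]} must be divisible by {stride} "
                f"({self.cfg.conv_blocks} pooling stages)"
            )
        return x.transpose(0, 3, 1, 2)  # channels-first

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = self._check_input(x)
        if self.cfg.variant == "four_branch":
            seqs = [
                b.forward(x[:, 3 * k : 3 * k + 3], train)
                for k, b in enumerate(self.branches)
            ]
            seq = np.concatenate(seqs, axis=2)
        else:
            seq = self.branches[0].forward(x, train)
        h = self.lstm.forward(seq, train)
        h = self.pool.forward(h, train)
        h = self.fc1.forward(h, train)
        h = self.act.forward(h, train)
        return self.fc2.forward(h, train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.fc2.backward(grad)
        g = self.act.backward(g)
        g = self.fc1.backward(g)
        g = self.pool.backward(g)
        g = self.lstm.backward(g)
        if self.cfg.variant == "four_branch":
            d = self.branches[0].out_dim
            for k, b in enumerate(self.branches):
                b.backward(g[:, :, k * d : (k + 1) * d])
        else:
            self.branches[0].backward(g)

    # -- inference --------------------------------------------------------
    def set_output_scaling(self, mean, sd) -> None:
        self.output_mean = np.asarray(mean, dtype=float).reshape(self.cfg.outputs)
        self.output_sd = np.asarray(sd, dtype=float).reshape(self.cfg.outputs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict (SBP, DBP) in mmHg for a batch of channels-last images.

        Deterministic for fixed weights (evaluation mode: batch-norm uses
        running statistics).
        """
        raw = self.forward(x, train=False)
        out = raw * self.output_sd + self.output_mean
        if not np.all(np.isfinite(out)):
            raise ShapeError("non-finite prediction; model weights are corrupt")
        return out


def build_model(cfg: ModelConfig, in_channels: int | None = None) -> ACNNBiLSTM:
    """Build the regressor for a config, checking variant/input consistency."""
    return ACNNBiLSTM(cfg, in_channels)


def predict(model: ACNNBiLSTM, inputs: np.ndarray) -> np.ndarray:
    """(SBP, DBP) predictions in mmHg, one pair per input image."""
    return model.predict(inputs)
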