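"""3D encoder-decoder (U-Net style) segmentation network.

The reference architecture is a 5-level 3D U-Net with (32, 64, 128, 256, 512)
encoder filters, the mirrored decoder, stride-2 downsampling and PReLU
activations, mapping a 3-channel patch (T1 pre, T1 post-gadolinium, FLAIR)
to a single-channel per-voxel probability map of the same spatial shape.

Each level applies two 3x3x3 convolutions, each followed by instance
normalization and PReLU; downsampling uses a stride-2 first convolution,
upsampling uses nearest-neighbour interpolation followed by convolution,
and skip connections are concatenated channel-wise. The terminal layer is a
1x1x1 convolution with a sigmoid. Width and depth are configurable so the
test profile can run a tiny network on CPU.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["NetworkConfig", "UNet3D", "build_model", "predict_patch",
           "save_checkpoint", "load_checkpoint"]

DEFAULT_ENCODER = (32, 64, 128, 256, 512)
DEFAULT_DECODER = (512, 256, 128, 64, 32)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters."""

    in_channels: int = 3
    out_channels: int = 1
    encoder_filters: tuple[int, ...] = DEFAULT_ENCODER
    decoder_filters: tuple[int, ...] = DEFAULT_DECODER
    stride: int = 2
    activation: str = "prelu"
    dtype: str = "float32"  # parameter precision; float64 for gradient checks

    def __post_init__(self):
        self.encoder_filters = tuple(self.encoder_filters)
        self.decoder_filters = tuple(self.decoder_filters)
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError(
                "encoder_filters and decoder_filters must have equal length"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.activation.lower() != "prelu":
            raise ValueError("only PReLU activation is supported")

    @property
    def levels(self) -> int:
        return len(self.encoder_filters)

    @property
    def min_divisor(self) -> int:
        """Input edges must be divisible by stride^(levels-1)."""
        return self.stride ** (self.levels - 1)


def _he_init(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class _ConvBlock:
    """conv -> instance norm -> PReLU."""

    def __init__(self, rng, cin, cout, kernel=3, stride=1, dtype=np.float32):
        self.stride = stride
        self.w = nn.Parameter(
            _he_init(rng, cin * kernel**3, (cout, cin, kernel, kernel, kernel), dtype)
        )
        self.b = nn.Parameter(np.zeros(cout, dtype=dtype))
        self.gamma = nn.Parameter(np.ones(cout, dtype=dtype))
        self.beta = nn.Parameter(np.zeros(cout, dtype=dtype))
        self.alpha = nn.Parameter(np.full(cout, 0.25, dtype=dtype))

    def __call__(self, x):
        x = nn.conv3d(x, self.w, self.b, stride=self.stride)
        x = nn.instance_norm(x, self.gamma, self.beta)
        return nn.prelu(x, self.alpha)

    def parameters(self):
        return [self.w, self.b, self.gamma, self.beta, self.alpha]


class UNet3D:
    """Configurable-width 3D U-Net mapping (N, C, E, E, E) -> (N, 1, E, E, E)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        dtype = np.dtype(config.dtype).type
        enc, dec = config.encoder_filters, config.decoder_filters
        L = config.levels
        self.enc_blocks = []
        cin = config.in_channels
        for i, f in enumerate(enc):
            stride = config.stride if i > 0 else 1
            self.enc_blocks.append(
                (
                    _ConvBlock(rng, cin, f, stride=stride, dtype=dtype),
                    _ConvBlock(rng, f, f, dtype=dtype),
                )
            )
            cin = f
        self.dec_blocks = []
        # decoder level i consumes upsampled features + skip from encoder
        for i in range(1, L):
            f = dec[i]
            skip = enc[L - 1 - i]
            cin_dec = (dec[i - 1] if i > 1 else enc[-1]) + skip
            self.dec_blocks.append(
                (
                    _ConvBlock(rng, cin_dec, f, dtype=dtype),
                    _ConvBlock(rng, f, f, dtype=dtype),
                )
            )
        self.head_w = nn.Parameter(
            _he_init(rng, dec[-1], (config.out_channels, dec[-1], 1, 1, 1), dtype)
        )
        self.head_b = nn.Parameter(np.zeros(config.out_channels, dtype=dtype))

    def parameters(self):
        ps = []
        for b1, b2 in self.enc_blocks + self.dec_blocks:
            ps += b1.parameters() + b2.parameters()
        ps += [self.head_w, self.head_b]
        return ps

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        edge = x.data.shape[2]
        if any(s % self.config.min_divisor for s in x.data.shape[2:]):
            raise ValueError(
                f"input edges {x.data.shape[2:]} must be divisible by "
                f"{self.config.min_divisor} for {self.config.levels} levels"
            )
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.data.shape[1]}"
            )
        x = nn.moveaxis(x, 1, -1)  # channels-last internally (cache-friendly convs)
        skips = []
        for b1, b2 in self.enc_blocks:
            x = b2(b1(x))
            skips.append(x)
        for i, (b1, b2) in enumerate(self.dec_blocks):
            x = nn.upsample_nearest(x, self.config.stride)
            x = nn.concat(x, skips[-(i + 2)])
            x = b2(b1(x))
        logits = nn.conv3d(x, self.head_w, self.head_b, stride=1)
        del edge
        return nn.moveaxis(nn.sigmoid(logits), -1, 1)

    __call__ = forward

    # ---- checkpointing ---------------------------------------------------

    def state_dict(self) -> dict:
        return {i: p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[i], dtype=p.data.dtype).copy()


def build_model(config: NetworkConfig, rng: np.random.Generator) -> UNet3D:
    """Construct a randomly initialized network."""
    return UNet3D(config, rng)


def predict_patch(model: UNet3D, patch_batch: np.ndarray) -> np.ndarray:
    """Forward a (N, C, E, E, E) batch; returns per-voxel probabilities."""
    batch = np.asarray(patch_batch)
    if batch.ndim != 5:
        raise ValueError("expected a 5D (N, C, D, H, W) batch")
    if not np.issubdtype(batch.dtype, np.floating):
        batch = batch.astype(np.float32)
    with nn.no_grad():
        return model(nn.Tensor(batch)).data


def save_checkpoint(path, model: UNet3D, extra: dict | None = None) -> None:
    payload = {"config": model.config, "state": model.state_dict(),
               "extra": extra or {}}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> tuple[UNet3D, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = UNet3D(payload["config"], np.random.default_rng(0))
    model.load_state_dict(payload["state"])
    return model, payload["extra"]
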