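"""CMM-Net assembly and the plain U-Net baseline.

The network is a four-level U-shaped encoder/decoder.  The encoder holds
eight 3x3 convolutions (two per level) and three 2x2 max poolings; a pyramid
pooling module follows each of the first three encoder levels, and its
concatenated output feeds both the next level and the matching skip
connection.  The decoder holds three bilinear 2x upsamplings, seven
convolutions (two per stage plus the classification head) and a pixelwise
softmax.  Encoder levels use dilation rates [6, 5, 4, 3] (shallow to deep),
decoder stages [4, 5, 6] (deep to shallow).  Every 3x3 convolution is
followed by batch normalization and ReLU; the bias-free pyramid bottleneck
1x1 convolutions are as well.

Because the network is fully convolutional, the trainable-parameter count is
a pure function of the channel configuration — independent of the input
size, of the dilation rates, and of the pyramid pooled sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .building_blocks import PyramidPooling
from .nn import autograd as ag

__all__ = [
    "NetworkConfig",
    "SegmentationModel",
    "build_cmm_net",
    "build_unet_baseline",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "skin_config",
    "brain_config",
    "retina_config",
    "phantom_config",
]

#: Per-level encoder channel widths.  Calibrated so that the configurations
#: shipped below reproduce the published trainable-parameter counts exactly
#: (10,246,562 at bottleneck 64 and 13,221,794 at bottleneck 128); the
#: decoder mirrors the first three entries.
DEFAULT_ENCODER_CHANNELS = (32, 96, 256, 512)


def default_pooled_sizes(max_scale: int) -> list[int]:
    """Four pyramid sizes {max, max//3, 4, 1}; 48 -> [48, 16, 4, 1].

    Small max scales where those collide fall back to octave spacing
    {max, max/2, max/4, 1}."""
    for sizes in ([max_scale, max_scale // 3, 4, 1],
                  [max_scale, max_scale // 2, max_scale // 4, 1]):
        if sorted(sizes, reverse=True) == sizes and len(set(sizes)) == 4:
            return sizes
    raise ValueError(f"cannot derive 4 distinct pyramid sizes from {max_scale}")


@dataclass
class NetworkConfig:
    """Complete hyper-parameter record; the model (and its parameter count)
    is a pure function of this object."""

    input_height: int = 192
    input_width: int = 256
    input_channels: int = 3
    num_classes: int = 2
    levels: int = 4
    encoder_channels: list[int] = field(
        default_factory=lambda: list(DEFAULT_ENCODER_CHANNELS))
    ppm_bottleneck_channels: int = 64
    ppm_max_scale: int = 64
    ppm_pooled_sizes: list[int] | None = None
    encoder_dilation_rates: list[int] = field(default_factory=lambda: [6, 5, 4, 3])
    decoder_dilation_rates: list[int] = field(default_factory=lambda: [4, 5, 6])
    use_ppm_per_level: bool = True

    def __post_init__(self):
        if self.levels != 4:
            raise ValueError("the architecture is defined for 4 levels")
        if len(self.encoder_channels) != self.levels:
            raise ValueError("encoder_channels must list one width per level")
        if len(self.encoder_dilation_rates) != self.levels:
            raise ValueError("encoder_dilation_rates must have length = levels")
        if len(self.decoder_dilation_rates) != self.levels - 1:
            raise ValueError("decoder_dilation_rates must have length = levels - 1")
        div = 2 ** (self.levels - 1)
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input dims must be divisible by {div}, got "
                f"{self.input_height}x{self.input_width}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if any(r < 1 for r in self.encoder_dilation_rates + self.decoder_dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if self.ppm_pooled_sizes is None:
            self.ppm_pooled_sizes = default_pooled_sizes(self.ppm_max_scale)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown NetworkConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class SegmentationModel(nn.Module):
    """The assembled encoder/decoder network.

    ``forward`` maps an (N, C, H, W) tensor to per-pixel class probabilities
    (N, num_classes, H, W) that sum to one over the class axis, for any H, W
    divisible by 8.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.encoder_channels
        enc_r = config.encoder_dilation_rates
        dec_r = config.decoder_dilation_rates
        b = config.ppm_bottleneck_channels

        h, w = config.input_height, config.input_width
        ins = config.input_channels
        skip_channels = []
        for lvl in range(4):
            setattr(self, f"enc{lvl}a",
                    nn.ConvBNReLU(ins, c[lvl], dilation=enc_r[lvl], rng=rng))
            setattr(self, f"enc{lvl}b",
                    nn.ConvBNReLU(c[lvl], c[lvl], dilation=enc_r[lvl], rng=rng))
            out = c[lvl]
            if config.use_ppm_per_level and lvl < 3:
                # pyramid sizes clamped to the level's feature-map side so
                # that pooling never has to exceed the input resolution
                side = min(h, w) // 2 ** lvl
                sizes = []
                for s in config.ppm_pooled_sizes:
                    s = min(s, side)
                    while s in sizes:   # keep the 4 levels distinct
                        s -= 1
                    sizes.append(max(s, 1))
                setattr(self, f"ppm{lvl}", PyramidPooling(c[lvl], b, sizes, rng=rng))
                out = c[lvl] + len(sizes) * b
            if lvl < 3:
                skip_channels.append(out)
            ins = out

        prev = ins  # bottom level output (no PPM after level 4)
        for i, lvl in enumerate((2, 1, 0)):
            d = c[lvl]
            setattr(self, f"up{lvl}",
                    nn.ConvBNReLU(prev, d, dilation=dec_r[i], rng=rng))
            setattr(self, f"dec{lvl}",
                    nn.ConvBNReLU(d + skip_channels[lvl], d,
                                  dilation=dec_r[i], rng=rng))
            prev = d
        self.head = nn.Conv2d(prev, config.num_classes, kernel_size=3,
                              bias=True, rng=rng)

    def forward(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(x)
        cfg = self.config
        skips = []
        for lvl in range(4):
            x = getattr(self, f"enc{lvl}a")(x)
            x = getattr(self, f"enc{lvl}b")(x)
            if cfg.use_ppm_per_level and lvl < 3:
                x = getattr(self, f"ppm{lvl}")(x)
            if lvl < 3:
                skips.append(x)
                x = ag.max_pool2d(x)
        for lvl in (2, 1, 0):
            _, _, h, w = x.data.shape
            x = ag.linmap2d(x, nn.resize_matrix(2 * h, h), nn.resize_matrix(2 * w, w))
            x = getattr(self, f"up{lvl}")(x)
            x = ag.concat([x, skips[lvl]], axis=1)
            x = getattr(self, f"dec{lvl}")(x)
        x = self.head(x)
        return ag.softmax_channels(x)

    # -- convenience inference --------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Foreground-probability map for one H x W x C (or H x W) image."""
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        x = img.transpose(2, 0, 1)[None]
        was_training = self.training
        self.eval()
        probs = self.forward(x).data
        self.train(was_training)
        return probs[0, 1]

    def predict_mask(self, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(image) >= threshold).astype(np.uint8)


def build_cmm_net(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Assemble CMM-Net (pyramid pooling at every encoder level)."""
    if not config.use_ppm_per_level:
        config = dataclasses.replace(config, use_ppm_per_level=True)
    return SegmentationModel(config, seed=seed)


def build_unet_baseline(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """The plain four-level U-Net: no pyramid pooling, all dilation rates 1."""
    config = dataclasses.replace(
        config, use_ppm_per_level=False,
        encoder_dilation_rates=[1] * config.levels,
        decoder_dilation_rates=[1] * (config.levels - 1))
    return SegmentationModel(config, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars (conv weights/biases, BN scale/shift)."""
    return model.num_parameters()


def save_checkpoint(model: SegmentationModel, path):
    state = model.state_dict()
    state["config_json"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, config: NetworkConfig | None = None) -> SegmentationModel:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files if k != "config_json"}
        stored = NetworkConfig.from_dict(
            json.loads(bytes(data["config_json"]).decode()))
    if config is not None and config.to_dict() != stored.to_dict():
        raise ValueError("checkpoint was trained with a different NetworkConfig")
    model = SegmentationModel(stored)
    model.load_state_dict(state)
    return model


# -- shipped presets (Table-7-calibrated) ---------------------------------

def skin_config() -> NetworkConfig:
    """Dermoscopy: 192x256 RGB, pyramid bottleneck 64, max scale 64."""
    return NetworkConfig(input_height=192, input_width=256,
                         ppm_bottleneck_channels=64, ppm_max_scale=64)


def brain_config() -> NetworkConfig:
    """MR slices: 192x192 three-channel stacks, bottleneck 64, max scale 48."""
    return NetworkConfig(input_height=192, input_width=192,
                         ppm_bottleneck_channels=64, ppm_max_scale=48)


def retina_config(dilated: bool = False) -> NetworkConfig:
    """Fundus patches: 128x128 RGB, bottleneck 128, max scale 32.

    The thin-vessel task performs better without dilation (small receptive
    fields suit thin targets), so rates default to 1; pass ``dilated=True``
    for the [6,5,4,3]/[4,5,6] variant.  Both share one parameter count.
    """
    kw = {}
    if not dilated:
        kw = dict(encoder_dilation_rates=[1, 1, 1, 1],
                  decoder_dilation_rates=[1, 1, 1])
    return NetworkConfig(input_height=128, input_width=128,
                         ppm_bottleneck_channels=128, ppm_max_scale=32, **kw)


def phantom_config(size: int = 64) -> NetworkConfig:
    """Reduced-width configuration for desk-scale phantom experiments."""
    return NetworkConfig(input_height=size, input_width=size,
                         encoder_channels=[8, 16, 32, 64],
                         ppm_bottleneck_channels=8, ppm_max_scale=16,
                         encoder_dilation_rates=[6, 5, 4, 3],
                         decoder_dilation_rates=[4, 5, 6])
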