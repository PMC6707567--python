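"""Network assembly: the full residual/dilated/attention encoder-decoder
and its three single-component ablations, built deterministically from a
:class:`ModelConfig`.

Wiring
------
* Encoder: 6 residual units; unit 1 keeps resolution (stride 1), units 2-6
  halve it (stride 2), so the bottleneck side is input_side / 32.
* Bridge: six parallel 3x3 dilated convolutions (r = 1, 2, 4, 8, 16, 32)
  whose outputs are summed and upsampled by 2 (or, with the bridge disabled,
  one plain 3x3 conv block followed by the same upsample).
* Decoder: 5 stages; each upsamples by 2 (the first upsample is the
  bridge's), gates the matching encoder skip with an attention gate (or
  passes it through raw), concatenates, and applies a stride-1 residual
  unit.
* Head: 1x1 convolution + sigmoid -> one probability channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .blocks import BRIDGE_DILATIONS

__all__ = [
    "ModelConfig",
    "LayerInfo",
    "NetworkDescription",
    "SegmentationNet",
    "build_model",
    "forward",
    "VARIANTS",
]

ENCODER_FILTERS = (32, 64, 128, 256, 512, 512)
DECODER_FILTERS = (512, 256, 128, 64, 32)

#: variant name -> (use_residual, use_dilated_bridge, use_attention_gates)
VARIANTS = {
    "rdau": (True, True, True),
    "rau": (True, False, True),
    "dau": (False, True, True),
    "rdu": (True, True, False),
}


@dataclass
class ModelConfig:
    """Deterministic architectural description of one network."""

    input_side: int = 128
    input_channels: int = 1
    use_residual: bool = True
    use_dilated_bridge: bool = True
    use_attention_gates: bool = True
    encoder_filters: tuple = ENCODER_FILTERS
    decoder_filters: tuple = DECODER_FILTERS
    seed: int = 0

    def __post_init__(self):
        self.encoder_filters = tuple(self.encoder_filters)
        self.decoder_filters = tuple(self.decoder_filters)
        if self.input_side % 32 != 0:
            raise ValueError(
                f"input_side must be divisible by 32 (five halvings), "
                f"got {self.input_side}")
        if len(self.encoder_filters) != 6 or len(self.decoder_filters) != 5:
            raise ValueError("need 6 encoder and 5 decoder filter counts")

    @property
    def variant(self) -> str:
        flags = (self.use_residual, self.use_dilated_bridge,
                 self.use_attention_gates)
        for name, f in VARIANTS.items():
            if f == flags:
                return name
        return "custom"

    @classmethod
    def for_variant(cls, name: str, **kwargs) -> "ModelConfig":
        try:
            r, d, a = VARIANTS[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}")
        return cls(use_residual=r, use_dilated_bridge=d,
                   use_attention_gates=a, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        d["decoder_filters"] = list(self.decoder_filters)
        d["variant"] = self.variant
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        variant = d.pop("variant", None)
        if variant and variant != "custom":
            r, da, a = VARIANTS[variant.lower()]
            d.setdefault("use_residual", r)
            d.setdefault("use_dilated_bridge", da)
            d.setdefault("use_attention_gates", a)
        return cls(**d)


@dataclass(frozen=True)
class LayerInfo:
    kind: str
    input_shape: tuple
    output_shape: tuple
    n_params: int


@dataclass
class NetworkDescription:
    layers: list = field(default_factory=list)
    total_params: int = 0

    def add(self, kind, in_shape, out_shape, n_params):
        self.layers.append(LayerInfo(kind, tuple(in_shape), tuple(out_shape),
                                     int(n_params)))
        self.total_params += int(n_params)


# ---------------------------------------------------------------------------
# sub-modules

class ResidualUnit(nn.Module):
    """conv(S)-BN-ReLU-conv-BN + projected shortcut, ReLU after the add."""

    def __init__(self, in_ch, out_ch, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.shortcut = None
        if in_ch != out_ch or stride != 1:
            self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                      bias=False)

    def forward(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        s = self.shortcut(x) if self.shortcut is not None else x
        return nn.relu(nn.add(h, s))


class PlainUnit(nn.Module):
    """conv(S)-BN-ReLU-conv-BN-ReLU, no shortcut (residual ablation)."""

    def __init__(self, in_ch, out_ch, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(h)))


class DilatedBridge(nn.Module):
    """Six parallel dilated 3x3 convs summed, then nearest upsample x2."""

    def __init__(self, channels, rng):
        super().__init__()
        for r in BRIDGE_DILATIONS:
            setattr(self, f"branch_r{r}",
                    nn.Conv2d(channels, channels, 3, rng, dilation=r))

    def forward(self, x):
        total = None
        for r in BRIDGE_DILATIONS:
            out = nn.relu(getattr(self, f"branch_r{r}")(x))
            total = out if total is None else nn.add(total, out)
        return nn.upsample_nearest(total, 2)


class PlainBridge(nn.Module):
    """Single plain 3x3 conv block + upsample x2 (bridge ablation)."""

    def __init__(self, channels, rng):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, rng)

    def forward(self, x):
        return nn.upsample_nearest(nn.relu(self.conv(x)), 2)


class AttentionGate(nn.Module):
    """One-channel multiplicative gate from equal-resolution h and g."""

    def __init__(self, h_ch, g_ch, rng, inter_ch=None):
        super().__init__()
        inter = inter_ch if inter_ch is not None else max(h_ch // 2, 1)
        self.wh = nn.Conv2d(h_ch, inter, 1, rng, bias=False)
        self.wg = nn.Conv2d(g_ch, inter, 1, rng, bias=False)
        self.b_hg = nn.Parameter(np.zeros(inter, dtype=np.float32))
        self.wint = nn.Conv2d(inter, inter, 1, rng)
        self.wk = nn.Conv2d(inter, 1, 1, rng)

    def forward(self, h, g):
        if h.shape[1:3] != g.shape[1:3]:
            raise ValueError(
                f"attention gate inputs differ spatially: {h.shape[1:3]} vs "
                f"{g.shape[1:3]}")
        mixed = nn.relu(nn.add(nn.add(self.wh(h), self.wg(g)), self.b_hg))
        alpha = nn.sigmoid(self.wk(self.wint(mixed)))
        return nn.mul(alpha, h)


class SegmentationNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        Unit = ResidualUnit if config.use_residual else PlainUnit

        enc = config.encoder_filters
        in_ch = config.input_channels
        for i, (f, s) in enumerate(zip(enc, (1, 2, 2, 2, 2, 2)), start=1):
            setattr(self, f"enc{i}", Unit(in_ch, f, rng, stride=s))
            in_ch = f

        if config.use_dilated_bridge:
            self.bridge = DilatedBridge(enc[-1], rng)
        else:
            self.bridge = PlainBridge(enc[-1], rng)

        # decoder stage i consumes the upsampled deeper signal plus the
        # encoder skip of matching resolution (enc5 ... enc1)
        dec = config.decoder_filters
        signal_ch = enc[-1]
        for i, f in enumerate(dec, start=1):
            skip_ch = enc[4 - (i - 1)]
            if config.use_attention_gates:
                setattr(self, f"ag{i}", AttentionGate(skip_ch, signal_ch, rng))
            setattr(self, f"dec{i}", Unit(skip_ch + signal_ch, f, rng, stride=1))
            signal_ch = f

        self.head = nn.Conv2d(dec[-1], 1, 1, rng)

    def encoder_outputs(self, x):
        outs = []
        h = x
        for i in range(1, 7):
            h = getattr(self, f"enc{i}")(h)
            outs.append(h)
        return outs

    def forward(self, x):
        skips = self.encoder_outputs(x)
        signal = self.bridge(skips[5])
        for i in range(1, 6):
            skip = skips[5 - i]
            if i > 1:
                signal = nn.upsample_nearest(signal, 2)
            if self.config.use_attention_gates:
                skip = getattr(self, f"ag{i}")(skip, signal)
            fused = nn.concat_channels([signal, skip])
            signal = getattr(self, f"dec{i}")(fused)
        return nn.sigmoid(self.head(signal))


# ---------------------------------------------------------------------------
# public API

def _count(module):
    return module.num_parameters()


def describe(model: SegmentationNet) -> NetworkDescription:
    """Trace a dummy forward pass and record per-block shape/parameter info."""
    cfg = model.config
    side = cfg.input_side
    desc = NetworkDescription()
    x = nn.Tensor(np.zeros((1, side, side, cfg.input_channels), dtype=np.float32))
    was_training = model.training
    model.eval()
    skips = model.encoder_outputs(x)
    prev_shape = x.shape
    for i, out in enumerate(skips, start=1):
        unit = getattr(model, f"enc{i}")
        kind = "residual_unit" if cfg.use_residual else "plain_unit"
        desc.add(f"encoder_{kind}_{i}", prev_shape[1:], out.shape[1:], _count(unit))
        prev_shape = out.shape
    signal = model.bridge(skips[5])
    kind = "dilated_bridge" if cfg.use_dilated_bridge else "plain_bridge"
    desc.add(kind, skips[5].shape[1:], signal.shape[1:], _count(model.bridge))
    for i in range(1, 6):
        skip = skips[5 - i]
        if i > 1:
            signal = nn.upsample_nearest(signal, 2)
        if cfg.use_attention_gates:
            ag = getattr(model, f"ag{i}")
            gated = ag(skip, signal)
            desc.add(f"attention_gate_{i}", skip.shape[1:], gated.shape[1:],
                     _count(ag))
            skip = gated
        fused = nn.concat_channels([signal, skip])
        unit = getattr(model, f"dec{i}")
        out = unit(fused)
        kind = "residual_unit" if cfg.use_residual else "plain_unit"
        desc.add(f"decoder_{kind}_{i}", fused.shape[1:], out.shape[1:],
                 _count(unit))
        signal = out
    out = nn.sigmoid(model.head(signal))
    desc.add("head_1x1_sigmoid", signal.shape[1:], out.shape[1:],
             _count(model.head))
    model.train(was_training)
    return desc


def build_model(config: ModelConfig):
    """Build a network from ``config``; returns (description, model)."""
    model = SegmentationNet(config)
    return describe(model), model


def forward(model: SegmentationNet, images: np.ndarray) -> np.ndarray:
    """Run a batch through the network.

    ``images``: (N, side, side) or (N, side, side, 1) floats in [0, 1].
    Returns per-pixel lesion probabilities of shape (N, side, side).
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    side = model.config.input_side
    if images.shape[1:3] != (side, side):
        raise ValueError(
            f"expected {side}x{side} inputs, got {images.shape[1:3]}")
    x = nn.Tensor(images)
    was_training = model.training
    model.eval()
    out = model(x)
    model.train(was_training)
    return np.asarray(out.data)[..., 0]
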