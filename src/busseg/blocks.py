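"""Pure, shape-contracted building blocks: residual units, dilated
convolution (with its receptive-field accounting), the six-branch dilated
bridge and the attention gate.

All feature maps here are single images indexed (row, col, channel) with
row 0 at the top.  Convolution kernels use the (kh, kw, in_channels,
out_channels) layout; batch-norm statistics are supplied explicitly so every
operation is a deterministic function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ResidualUnitSpec",
    "DilatedConvSpec",
    "AttentionGateSpec",
    "BRIDGE_DILATIONS",
    "receptive_field_side",
    "residual_unit",
    "dilated_conv",
    "dilated_bridge",
    "attention_gate",
    "init_residual_unit_weights",
    "init_dilated_conv_weights",
    "init_attention_gate_weights",
]

#: dilation rates of the six bridge branches
BRIDGE_DILATIONS = (1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class ResidualUnitSpec:
    """Residual unit: conv(S)-BN-ReLU-conv-BN plus a (projected) shortcut."""
    filters_n: int
    stride_S: int = 1
    kernel_size: int = 3
    role: str = "encoder"

    def __post_init__(self):
        if self.filters_n < 1:
            raise ValueError("filters_n must be positive")
        if self.stride_S not in (1, 2):
            raise ValueError(f"stride_S must be 1 or 2, got {self.stride_S}")
        if self.role == "decoder" and self.stride_S != 1:
            raise ValueError("decoder residual units must have stride 1")


@dataclass(frozen=True)
class DilatedConvSpec:
    kernel_size_K: int = 3
    dilation_r: int = 1
    filters: int = 1

    def __post_init__(self):
        if self.dilation_r < 1:
            raise ValueError(f"dilation_r must be >= 1, got {self.dilation_r}")
        if self.kernel_size_K % 2 != 1:
            raise ValueError("kernel_size_K must be odd")


@dataclass(frozen=True)
class AttentionGateSpec:
    intermediate_channels: int = 1

    def __post_init__(self):
        if self.intermediate_channels < 1:
            raise ValueError("intermediate_channels must be positive")


def receptive_field_side(kernel_size_K: int, dilation_r: int) -> int:
    """Side length of a dilated kernel's receptive field:
    (K + 1) * (r - 1) + K.  The field area is the square of this value.
    """
    if kernel_size_K < 1 or dilation_r < 1:
        raise ValueError("kernel size and dilation must be >= 1")
    return (kernel_size_K + 1) * (dilation_r - 1) + kernel_size_K


# ---------------------------------------------------------------------------
# array plumbing

def _batched(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float32)
    if fm.ndim == 2:
        fm = fm[:, :, None]
    if fm.ndim != 3:
        raise ValueError(f"feature map must be (rows, cols, channels), got {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm[None]


def _unbatched(x: nn.Tensor) -> np.ndarray:
    return np.asarray(x.data)[0]


def _kernel(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=np.float32)
    if k.ndim != 4:
        raise ValueError(f"kernel must be (kh, kw, in, out), got shape {k.shape}")
    return k


def _bn(x, bn_weights):
    c = x.shape[-1]
    gamma = bn_weights.get("gamma", np.ones(c, dtype=np.float32))
    beta = bn_weights.get("beta", np.zeros(c, dtype=np.float32))
    mean = np.asarray(bn_weights.get("mean", np.zeros(c)), dtype=np.float32)
    var = np.asarray(bn_weights.get("var", np.ones(c)), dtype=np.float32)
    return nn.batch_norm(nn.Tensor(x.data) if not isinstance(x, nn.Tensor) else x,
                         nn.Tensor(gamma), nn.Tensor(beta),
                         mean.copy(), var.copy(), training=False)


# ---------------------------------------------------------------------------
# operations

def residual_unit(fm: np.ndarray, spec: ResidualUnitSpec, weights: dict,
                  activation_after_add: bool = True) -> np.ndarray:
    """y = F(x) + shortcut(x) with F = conv(S)-BN-ReLU-conv-BN.

    The shortcut is a 1x1 convolution (kernel ``weights["shortcut"]``) with
    the same stride whenever the channel count or stride changes, identity
    otherwise.  A ReLU follows the addition.
    """
    x = nn.Tensor(_batched(fm))
    in_ch = x.shape[-1]
    s = spec.stride_S
    w1 = nn.Tensor(_kernel(weights["conv1"]))
    w2 = nn.Tensor(_kernel(weights["conv2"]))
    if w1.shape[-1] != spec.filters_n or w2.shape[-1] != spec.filters_n:
        raise ValueError("conv kernels disagree with spec.filters_n")

    h = nn.conv2d(x, w1, stride=s)
    h = _bn(h, weights.get("bn1", {}))
    h = nn.relu(h)
    h = nn.conv2d(h, w2, stride=1)
    h = _bn(h, weights.get("bn2", {}))

    needs_projection = (in_ch != spec.filters_n) or (s != 1)
    if needs_projection:
        if "shortcut" not in weights:
            raise ValueError(
                f"shortcut projection required: input has {in_ch} channels / "
                f"stride {s} but unit outputs {spec.filters_n} channels")
        ws = nn.Tensor(_kernel(weights["shortcut"]))
        short = nn.conv2d(x, ws, stride=s)
    else:
        short = x
    if short.shape != h.shape:
        raise ValueError(
            f"residual branch shapes differ: main {h.shape[1:]} vs "
            f"shortcut {short.shape[1:]}")
    y = nn.add(h, short)
    if activation_after_add:
        y = nn.relu(y)
    return _unbatched(y)


def dilated_conv(fm: np.ndarray, spec: DilatedConvSpec, weights: dict) -> np.ndarray:
    """ReLU(dilated same-padded cross-correlation + bias).

    Zero padding supplies out-of-range samples, so the output spatial size
    equals the input spatial size.
    """
    x = nn.Tensor(_batched(fm))
    k = _kernel(weights["kernel"])
    if k.shape[0] != spec.kernel_size_K or k.shape[-1] != spec.filters:
        raise ValueError("kernel shape disagrees with spec")
    bias = np.asarray(weights.get("bias", np.zeros(spec.filters)), dtype=np.float32)
    out = nn.conv2d(x, nn.Tensor(k), nn.Tensor(bias),
                    stride=1, dilation=spec.dilation_r)
    return _unbatched(nn.relu(out))


def dilated_bridge(fm: np.ndarray, specs, weights) -> np.ndarray:
    """Sum of the six dilated branches, then nearest upsample by 2.

    ``specs`` are the r = 1, 2, 4, 8, 16, 32 branches with equal kernel
    size and filter counts; ``weights`` is one weights dict per branch.
    """
    specs = list(specs)
    if tuple(s.dilation_r for s in specs) != BRIDGE_DILATIONS:
        raise ValueError(f"bridge requires dilations {BRIDGE_DILATIONS}")
    if len({(s.kernel_size_K, s.filters) for s in specs}) != 1:
        raise ValueError("bridge branches must share kernel size and filters")
    outs = [dilated_conv(fm, s, w) for s, w in zip(specs, weights)]
    shapes = {o.shape for o in outs}
    if len(shapes) != 1:
        raise ValueError(f"bridge branch outputs disagree in shape: {shapes}")
    total = nn.Tensor(_batched(sum(outs)))
    return _unbatched(nn.upsample_nearest(total, 2))


def attention_gate(h: np.ndarray, g: np.ndarray, spec: AttentionGateSpec,
                   weights: dict, return_alpha: bool = False):
    """Gate the encoder map ``h`` with a one-channel coefficient map.

    alpha = sigmoid(Wk [Wint relu(Wh h + Wg g + b_hg) + b_int] + b_k), all
    1x1 kernels; output = alpha * h broadcast over h's channels.  ``h`` and
    ``g`` must share spatial size — no interpolation happens inside.
    """
    ht = nn.Tensor(_batched(h))
    gt = nn.Tensor(_batched(g))
    if ht.shape[1:3] != gt.shape[1:3]:
        raise ValueError(
            f"attention gate inputs differ spatially: h {ht.shape[1:3]} vs "
            f"g {gt.shape[1:3]}")
    wh = _kernel(weights["Wh"])
    wg = _kernel(weights["Wg"])
    wint = _kernel(weights["Wint"])
    wk = _kernel(weights["Wk"])
    for name, w in (("Wh", wh), ("Wg", wg), ("Wint", wint), ("Wk", wk)):
        if w.shape[:2] != (1, 1):
            raise ValueError(f"{name} must have 1x1 spatial extent")
    b_hg = np.asarray(weights.get("b_hg", np.zeros(spec.intermediate_channels)),
                      dtype=np.float32)
    b_int = np.asarray(weights.get("b_int", np.zeros(spec.intermediate_channels)),
                       dtype=np.float32)
    b_k = np.asarray(weights.get("b_k", np.zeros(1)), dtype=np.float32)

    mixed = nn.add(nn.conv2d(ht, nn.Tensor(wh)),
                   nn.add(nn.conv2d(gt, nn.Tensor(wg)), nn.Tensor(b_hg)))
    inter = nn.conv2d(nn.relu(mixed), nn.Tensor(wint), nn.Tensor(b_int))
    alpha = nn.sigmoid(nn.conv2d(inter, nn.Tensor(wk), nn.Tensor(b_k)))
    gated = nn.mul(alpha, ht)
    if return_alpha:
        return _unbatched(gated), _unbatched(alpha)
    return _unbatched(gated)


# ---------------------------------------------------------------------------
# seeded weight initializers (He-normal kernels, zero biases / BN identity)

def _he(rng, kh, kw, cin, cout):
    return rng.normal(0.0, np.sqrt(2.0 / (kh * kw * cin)),
                      size=(kh, kw, cin, cout)).astype(np.float32)


def init_residual_unit_weights(rng: np.random.Generator, in_channels: int,
                               spec: ResidualUnitSpec) -> dict:
    k = spec.kernel_size
    w = {
        "conv1": _he(rng, k, k, in_channels, spec.filters_n),
        "conv2": _he(rng, k, k, spec.filters_n, spec.filters_n),
        "bn1": {}, "bn2": {},
    }
    if in_channels != spec.filters_n or spec.stride_S != 1:
        w["shortcut"] = _he(rng, 1, 1, in_channels, spec.filters_n)
    return w


def init_dilated_conv_weights(rng: np.random.Generator, in_channels: int,
                              spec: DilatedConvSpec) -> dict:
    return {
        "kernel": _he(rng, spec.kernel_size_K, spec.kernel_size_K,
                      in_channels, spec.filters),
        "bias": np.zeros(spec.filters, dtype=np.float32),
    }


def init_attention_gate_weights(rng: np.random.Generator, h_channels: int,
                                g_channels: int, spec: AttentionGateSpec) -> dict:
    m = spec.intermediate_channels
    return {
        "Wh": _he(rng, 1, 1, h_channels, m),
        "Wg": _he(rng, 1, 1, g_channels, m),
        "Wint": _he(rng, 1, 1, m, m),
        "Wk": _he(rng, 1, 1, m, 1),
        "b_hg": np.zeros(m, dtype=np.float32),
        "b_int": np.zeros(m, dtype=np.float32),
        "b_k": np.zeros(1, dtype=np.float32),
    }
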