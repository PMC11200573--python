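"""Architecture builders: attention U-Net enhancer, x4 upscaler, critics.

Three families make up the dual-GAN pipeline:

* ``build_gde`` — the degradation-enhancement generator: a U-Net whose
  encoder halves H, W and doubles channels per level (3x3 conv, stride 2),
  whose decoder mirrors it with 3x3 transposed convolutions, with skip
  connections between matching levels and an attention box (batch-norm ->
  activation -> operation-wise attention -> activation) after every encoder
  and decoder convolution. Spatial size is preserved end to end.
* ``build_gsr`` — the super-resolution generator: feature extractor,
  residual blocks (conv+BN -> PReLU -> conv+BN, residual sum), a conv+BN
  with a global skip from the extractor, then two conv + x2 pixel-shuffle
  stages and a channel-calibration conv down to 3 channels; maps H x W to
  4H x 4W.
* ``build_discriminator`` — a critic ladder of conv+BN+LeakyReLU blocks with
  channels doubling up to 8x the base width, reduced to a single per-image
  scalar in (0, 1). The low-resolution and full-resolution critics share
  this structure but are always built as independent parameter sets.

All builders are deterministic in (config, seed). The operation-wise
attention module applies several parallel channel-preserving candidate
operations (1x1/3x3/5x5 convolutions at dilations 1-2, plus average
pooling) and combines them with per-sample softmax weights predicted from a
globally pooled bottleneck gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from . import nn

__all__ = [
    "NetConfig", "OpAttention", "GDE", "GSR", "Critic",
    "build_gde", "build_gsr", "build_discriminator",
    "to_tensor", "to_images",
]


@dataclass(frozen=True)
class NetConfig:
    """Width/depth knobs for all three network families.

    Defaults follow the conventions of the cited base architectures
    (16 residual blocks for the upscaler, 4 U-Net levels); ``tiny()`` gives
    the reduced desk-scale configuration used throughout the test suite.
    """

    base_channels: int = 64
    depth: int = 4
    n_residual_blocks: int = 16
    n_attention_ops: int = 6
    scale: int = 4
    tiny_mode: bool = False

    def __post_init__(self):
        if self.base_channels < 4:
            raise ValueError(f"base_channels must be >= 4, got {self.base_channels}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        s = self.scale
        if s < 2 or (s & (s - 1)) != 0:
            raise ValueError(f"scale must be a power of 2 >= 2, got {s}")
        if not (1 <= self.n_attention_ops <= 6):
            raise ValueError("n_attention_ops must be in 1..6")

    @staticmethod
    def tiny() -> "NetConfig":
        return NetConfig(base_channels=8, depth=2, n_residual_blocks=4,
                         n_attention_ops=3, scale=4, tiny_mode=True)


# -- image <-> tensor plumbing ----------------------------------------------

def to_tensor(images) -> Tensor:
    """H x W x 3 [0,1] image(s) (single or N-stack) -> N x C x H x W Tensor."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr.transpose(0, 3, 1, 2))


def to_images(t: Tensor, clip: bool = True) -> np.ndarray:
    """N x C x H x W Tensor -> N x H x W x C array (optionally clipped to [0,1])."""
    arr = t.data.transpose(0, 2, 3, 1)
    return np.clip(arr, 0.0, 1.0) if clip else arr.copy()


# -- operation-wise attention -------------------------------------------------

# candidate operation menu: (kernel, dilation) pairs, "pool" = 3x3 averaging
_CANDIDATES = [(1, 1), (3, 1), "pool", (5, 1), (3, 2), (5, 2)]


class OpAttention(nn.Module):
    """Attention-weighted sum over parallel candidate operations."""

    def __init__(self, channels: int, n_ops: int, rng: np.random.Generator):
        super().__init__()
        self.n_ops = n_ops
        ops = []
        for spec in _CANDIDATES[:n_ops]:
            if spec == "pool":
                ops.append(nn.AvgPool3x3())
            else:
                k, d = spec
                ops.append(nn.Conv2d(channels, channels, k, dilation=d, rng=rng))
        self.ops = nn.ModuleList(ops)
        hidden = max(4, channels // 2)
        self.gate1 = nn.Linear(channels, hidden, rng=rng)
        self.gate2 = nn.Linear(hidden, n_ops, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3))                      # (N, C)
        logits = self.gate2(self.gate1(pooled).leaky_relu(0.2))
        w = logits.softmax(axis=1)                        # (N, n_ops)
        out = None
        for i, op in enumerate(self.ops):
            wi = w[:, i:i + 1].reshape(N, 1, 1, 1)
            term = wi * op(x)
            out = term if out is None else out + term
        return out


class AttBox(nn.Module):
    """batch-norm -> activation -> operation-wise attention -> activation."""

    def __init__(self, channels: int, n_ops: int, rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm2d(channels)
        self.att = OpAttention(channels, n_ops, rng)

    def forward(self, x):
        return self.att(self.bn(x).leaky_relu(0.2)).leaky_relu(0.2)


# -- GDE: attention U-Net enhancer --------------------------------------------

def _pad_to_multiple(x: Tensor, m: int):
    """Zero-pad bottom/right so H, W are divisible by m; returns (x, H, W)."""
    N, C, H, W = x.shape
    pb, pr = (-H) % m, (-W) % m
    if pb:
        x = concat([x, Tensor(np.zeros((N, C, pb, W)))], axis=2)
    if pr:
        x = concat([x, Tensor(np.zeros((N, C, x.shape[2], pr)))], axis=3)
    return x, H, W


class GDE(nn.Module):
    """U-Net with operation-wise attention; preserves spatial dimensions."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, d, n_ops = cfg.base_channels, cfg.depth, cfg.n_attention_ops
        enc_ch = [3] + [c * 2 ** i for i in range(d)]
        self.enc_convs = nn.ModuleList(
            [nn.Conv2d(enc_ch[i], enc_ch[i + 1], 3, stride=2, pad=1, rng=rng)
             for i in range(d)])
        self.enc_atts = nn.ModuleList(
            [AttBox(enc_ch[i + 1], n_ops, rng) for i in range(d)])
        dec_convs, dec_atts = [], []
        ch = enc_ch[-1]
        for i in range(d):
            out_ch = max(4, ch // 2)
            dec_convs.append(nn.ConvTranspose2d(ch, out_ch, rng=rng))
            dec_atts.append(AttBox(out_ch, n_ops, rng))
            # skip concat with the matching encoder feature (none at full res)
            skip_ch = enc_ch[d - 1 - i] if i < d - 1 else 0
            ch = out_ch + skip_ch
        self.dec_convs = nn.ModuleList(dec_convs)
        self.dec_atts = nn.ModuleList(dec_atts)
        # level-0 skip: the head sees the decoder output stacked with the
        # input image itself, so full-resolution detail has a direct path;
        # identity-initialized on those channels, the untrained enhancer is
        # (almost exactly) the identity map and training learns a correction
        self.head = nn.Conv2d(ch + 3, 3, 3, pad=1, rng=rng)
        self.head.weight.data *= 0.01
        for o in range(3):
            self.head.weight.data[o, ch + o, 1, 1] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        x, H, W = _pad_to_multiple(x, 2 ** self.cfg.depth)
        skips = []
        h = x
        for conv, att in zip(self.enc_convs, self.enc_atts):
            h = att(conv(h))
            skips.append(h)
        for i, (deconv, att) in enumerate(zip(self.dec_convs, self.dec_atts)):
            h = att(deconv(h))
            skip_idx = self.cfg.depth - 2 - i
            if skip_idx >= 0:
                h = concat([h, skips[skip_idx]], axis=1)
        out = self.head(concat([h, x], axis=1))
        return out[:, :, :H, :W]

    def parameter_groups(self) -> dict:
        """Named parameter groups {encoder, decoder, attention} for freezing."""
        groups = {"encoder": {}, "decoder": {}, "attention": {}}
        for name, p in self.named_parameters():
            if name.startswith("enc_convs."):
                groups["encoder"][name] = p
            elif name.startswith(("enc_atts.", "dec_atts.")):
                groups["attention"][name] = p
            else:  # dec_convs + head
                groups["decoder"][name] = p
        return groups


# -- GSR: residual / pixel-shuffle x4 upscaler --------------------------------

class _ResBlock(nn.Module):
    def __init__(self, c: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c, c, 3, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.act = nn.PReLU(c)
        self.conv2 = nn.Conv2d(c, c, 3, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)

    def forward(self, x):
        h = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        return x + h


class GSR(nn.Module):
    """Maps H x W x 3 to (scale*H) x (scale*W) x 3 via pixel shuffling."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.base_channels
        self.extract = nn.Conv2d(3, c, 3, pad=1, rng=rng)
        self.extract_act = nn.PReLU(c)
        self.blocks = nn.ModuleList(
            [_ResBlock(c, rng) for _ in range(cfg.n_residual_blocks)])
        self.post = nn.Conv2d(c, c, 3, pad=1, rng=rng)
        self.post_bn = nn.BatchNorm2d(c)
        n_stages = int(np.log2(cfg.scale))
        self.up_convs = nn.ModuleList(
            [nn.Conv2d(c, 4 * c, 3, pad=1, rng=rng) for _ in range(n_stages)])
        self.up_acts = nn.ModuleList([nn.PReLU(c) for _ in range(n_stages)])
        self.shuffle = nn.PixelShuffle(2)
        # channel calibration sees the learned features stacked with a fixed
        # bilinear upsample of the input; its weights start as the identity
        # on those three channels, so the untrained upscaler reproduces
        # plain interpolation and training learns the residual detail
        self.calibrate = nn.Conv2d(c + 3, 3, 3, pad=1, rng=rng)
        # start as (almost exactly) plain interpolation: identity taps on the
        # bilinear channels, feature taps scaled near zero so the residual
        # grows from nothing but every parameter still receives gradient
        self.calibrate.weight.data *= 0.01
        for o in range(3):
            self.calibrate.weight.data[o, c + o, 1, 1] = 1.0
        r = cfg.scale
        taps = 1.0 - np.abs(np.arange(2 * r) + 0.5 - r) / r
        kern = np.outer(taps, taps)
        w = np.zeros((3, 3, 2 * r, 2 * r))
        for ch in range(3):
            w[ch, ch] = kern
        self._bilinear_w = Tensor(w)   # fixed, non-trainable

    def _upsample(self, x: Tensor) -> Tensor:
        from .autograd import conv_transpose2d
        r = self.cfg.scale
        return conv_transpose2d(x, self._bilinear_w, stride=r, pad=r // 2,
                                output_padding=0)

    def forward(self, x: Tensor) -> Tensor:
        feat = self.extract_act(self.extract(x))
        h = feat
        for blk in self.blocks:
            h = blk(h)
        h = self.post_bn(self.post(h)) + feat          # global skip
        for conv, act in zip(self.up_convs, self.up_acts):
            h = act(self.shuffle(conv(h)))
        return self.calibrate(concat([h, self._upsample(x)], axis=1))


# -- discriminator -------------------------------------------------------------

class Critic(nn.Module):
    """Conv-block ladder reducing an image to one sigmoid score in (0, 1)."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.base_channels
        self.extract = nn.Conv2d(3, c, 3, pad=1, rng=rng)
        if cfg.tiny_mode:
            plan = [(1, 2), (2, 2), (4, 1), (8, 1)]
        else:
            plan = [(1, 2), (2, 1), (2, 2), (4, 1), (4, 2), (8, 1), (8, 2)]
        blocks = []
        cin = c
        for mult, stride in plan:
            cout = min(8 * c, mult * c)
            blocks.append(nn.Sequential(
                nn.Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng),
                nn.BatchNorm2d(cout),
                nn.LeakyReLU(0.2)))
            cin = cout
        self.blocks = nn.ModuleList(blocks)
        self.min_input = 2 * int(np.prod([s for _, s in plan]))
        self.dense1 = nn.Linear(cin, cin, rng=rng)
        self.dense2 = nn.Linear(cin, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, _, H, W = x.shape
        if min(H, W) < self.min_input:
            raise ValueError(
                f"critic input {H}x{W} below receptive-field minimum "
                f"{self.min_input}")
        h = self.extract(x).leaky_relu(0.2)
        for blk in self.blocks:
            h = blk(h)
        h = h.mean(axis=(2, 3))                        # (N, C)
        h = self.dense1(h).leaky_relu(0.2)
        score = self.dense2(h).sigmoid()               # (N, 1)
        return score.reshape(N)


# -- public builders -----------------------------------------------------------

def build_gde(cfg: NetConfig, seed: int = 0) -> GDE:
    return GDE(cfg, np.random.default_rng(seed))


def build_gsr(cfg: NetConfig, seed: int = 0) -> GSR:
    return GSR(cfg, np.random.default_rng(seed))


def build_discriminator(cfg: NetConfig, seed: int = 0) -> Critic:
    return Critic(cfg, np.random.default_rng(seed))
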