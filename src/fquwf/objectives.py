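"""The complete loss suite of the two-stage adversarial pipeline.

Stage DE (degradation enhancement) trains the enhancer against a
low-resolution critic with three terms:

    L_E = L_adv + lambda_I * L_identity + lambda_R * L_anchor

where the identity term |G(z) - z| (L1) keeps the enhancer from restyling
images that already look like the target domain, and the anchor term is a
mean-squared penalty tying the adapted (non-frozen) enhancer parameters to
their pretrained snapshot so adversarial adaptation cannot drift
catastrophically.

Stage SR trains the x4 upscaler with

    L_SR = L_adv + lambda_C * L_cycle

whose one-way cycle downsamples a real fundus image by 4, super-resolves
it, and compares to the original (L1) — no reverse generator is learned.

Macular fine-tuning optimizes the sum L_M = L_E + L_SR on macular patches.

Adversarial terms use the standard non-saturating binary cross-entropy
forms with critic outputs clamped to [1e-7, 1 - 1e-7]:

    d_loss = -E[log D(real)] - E[log(1 - D(fake))]
    g_loss = -E[log D(fake)]

Default weights: lambda_I = 0.5, lambda_R = 0.1, lambda_C = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor
from .degradations import bicubic_resample
from .networks import to_tensor

__all__ = [
    "LossWeights", "LossBreakdown",
    "adversarial_loss", "adversarial_d_loss", "adversarial_g_loss",
    "identity_loss", "weight_anchor_loss", "cycle_loss",
    "total_de_loss", "total_sr_loss", "total_finetune_loss",
    "PROB_EPS",
]

#: critic probabilities are clamped to [PROB_EPS, 1 - PROB_EPS] inside logs
PROB_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_I: float = 0.5
    lambda_R: float = 0.1
    lambda_C: float = 0.5

    def __post_init__(self):
        for name in ("lambda_I", "lambda_R", "lambda_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LossBreakdown:
    """Per-iteration loss components; ``total`` is the stage's weighted sum."""

    stage: str                     # "DE" | "SR" | "FT"
    adv_g: float = 0.0
    adv_d: float = 0.0
    identity: float = 0.0
    anchor: float = 0.0
    cycle: float = 0.0
    total: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_batch_tensor(batch) -> Tensor:
    if isinstance(batch, Tensor):
        return batch
    return to_tensor(batch)


def _scalar(x) -> float:
    return x.item() if isinstance(x, Tensor) else float(x)


def adversarial_d_loss(critic, real_batch, fake_batch) -> Tensor:
    """Critic loss -E[log D(real)] - E[log(1 - D(fake))]; fake is detached."""
    real = _as_batch_tensor(real_batch)
    fake = _as_batch_tensor(fake_batch)
    if real.shape[0] == 0 or fake.shape[0] == 0:
        raise ValueError("adversarial loss requires nonempty batches")
    d_real = critic(real).clamp(PROB_EPS, 1.0 - PROB_EPS)
    d_fake = critic(fake.detach()).clamp(PROB_EPS, 1.0 - PROB_EPS)
    return -(d_real.log().mean()) - ((1.0 - d_fake).log().mean())


def adversarial_g_loss(critic, fake_batch) -> Tensor:
    """Non-saturating generator loss -E[log D(fake)]; gradients reach the
    generator through the fake images."""
    fake = _as_batch_tensor(fake_batch)
    if fake.shape[0] == 0:
        raise ValueError("adversarial loss requires a nonempty batch")
    d_fake = critic(fake).clamp(PROB_EPS, 1.0 - PROB_EPS)
    return -(d_fake.log().mean())


def adversarial_loss(critic, real_batch, fake_batch):
    """Non-saturating GAN losses; returns (d_loss, g_loss) scalar Tensors.

    ``fake_batch`` is treated as a constant for the critic loss (detached)
    and as a variable for the generator loss, so backpropagating ``d_loss``
    touches only the critic and ``g_loss`` reaches the generator through
    the fake images.
    """
    d_loss = adversarial_d_loss(critic, real_batch, fake_batch)
    g_loss = adversarial_g_loss(critic, fake_batch)
    return d_loss, g_loss


def identity_loss(enhancer, batch) -> Tensor:
    """Mean absolute deviation of the enhancer from the identity map."""
    z = _as_batch_tensor(batch)
    if z.shape[0] == 0:
        raise ValueError("identity_loss requires a nonempty batch")
    return (enhancer(z) - z.detach()).abs().mean()


def weight_anchor_loss(current_params: dict, anchor_params: dict) -> Tensor:
    """Mean squared distance of anchored parameters from their snapshot.

    ``current_params`` maps names to live parameters (the non-frozen
    enhancer groups); ``anchor_params`` maps the same names to the stored
    pretrained arrays. The sum of squared differences is divided by the
    total number of anchored scalars.
    """
    if set(current_params) != set(anchor_params):
        raise ValueError("anchor parameter structure mismatch")
    n_total = sum(int(np.asarray(a).size) for a in anchor_params.values())
    if n_total == 0:
        return Tensor(0.0)
    acc = None
    for name, p in current_params.items():
        a = np.asarray(anchor_params[name], dtype=np.float64)
        if a.shape != p.data.shape:
            raise ValueError(f"anchor shape mismatch for {name}")
        term = ((p - Tensor(a)) ** 2.0).sum()
        acc = term if acc is None else acc + term
    return acc * (1.0 / n_total)


def cycle_loss(upscaler, fundus_batch) -> Tensor:
    """One-way cycle: |GSR(downsample_x4(x)) - x| averaged over the batch.

    Images with H or W not divisible by 4 are cropped to the largest
    multiple of 4 before the cycle.
    """
    arr = np.asarray(
        fundus_batch.data.transpose(0, 2, 3, 1)
        if isinstance(fundus_batch, Tensor) else fundus_batch, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[0] == 0:
        raise ValueError("cycle_loss requires a nonempty batch")
    H, W = arr.shape[1], arr.shape[2]
    Hc, Wc = (H // 4) * 4, (W // 4) * 4
    arr = arr[:, :Hc, :Wc, :]
    down = np.stack([bicubic_resample(im, 0.25) for im in arr])
    up = upscaler(to_tensor(down))
    target = to_tensor(arr)
    return (up - target).abs().mean()


def total_de_loss(components: dict, weights: LossWeights) -> LossBreakdown:
    """Composite enhancement loss: adv_g + lambda_I*identity + lambda_R*anchor."""
    adv_g = _scalar(components["adv_g"])
    ident = _scalar(components.get("identity", 0.0))
    anchor = _scalar(components.get("anchor", 0.0))
    total = adv_g + weights.lambda_I * ident + weights.lambda_R * anchor
    return LossBreakdown(stage="DE", adv_g=adv_g, identity=ident,
                         anchor=anchor, total=total,
                         adv_d=_scalar(components.get("adv_d", 0.0)))


def total_sr_loss(components: dict, weights: LossWeights) -> LossBreakdown:
    """Composite super-resolution loss: adv_g + lambda_C*cycle."""
    adv_g = _scalar(components["adv_g"])
    cyc = _scalar(components.get("cycle", 0.0))
    total = adv_g + weights.lambda_C * cyc
    return LossBreakdown(stage="SR", adv_g=adv_g, cycle=cyc, total=total,
                         adv_d=_scalar(components.get("adv_d", 0.0)))


def total_finetune_loss(de_breakdown: LossBreakdown,
                        sr_breakdown: LossBreakdown) -> LossBreakdown:
    """Macular fine-tuning loss: the sum of the two stage losses."""
    return LossBreakdown(
        stage="FT",
        adv_g=de_breakdown.adv_g + sr_breakdown.adv_g,
        adv_d=de_breakdown.adv_d + sr_breakdown.adv_d,
        identity=de_breakdown.identity,
        anchor=de_breakdown.anchor,
        cycle=sr_breakdown.cycle,
        total=de_breakdown.total + sr_breakdown.total,
    )
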