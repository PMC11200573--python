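"""Three-stage training scheme and the inference entry point.

The enhancer (GDE) and the x4 upscaler (GSR) are trained in sequence, each
against its own critic, then jointly fine-tuned on macular patches:

1. **Pretraining** — supervised mean-absolute-error reconstruction of clean
   low-resolution targets from degraded phantoms. This initializes GDE and
   yields the parameter snapshot used as the weight anchor.
2. **Stage DE** — adversarial adaptation of GDE against the low-resolution
   critic (real: x4-downsampled fundus patches; fake: enhanced UWF patches),
   with the encoder frozen and the identity and weight-anchor terms active.
3. **Stage SR** — GSR training against the full-resolution critic (real:
   fundus patches; fake: GSR(GDE(uwf))) plus the one-way cycle loss, with
   every GDE parameter frozen (GDE runs in eval mode so not even batch-norm
   statistics move).
4. **Macular fine-tuning** — joint optimization of both generators, nothing
   frozen, on patches whose centers are restricted to the macular region,
   minimizing the sum of the stage losses.

Optimization uses AdamW (lr 1e-3, betas (0.9, 0.999), eps 1e-8, decoupled
weight decay 1e-2) with the learning rate halved every ``lr_halving_period``
iterations. Patches are randomly cropped and augmented with 90-degree
rotations and flips. All stages checkpoint to ``<run_dir>/<stage>/final.npz``
with a JSON sidecar and are exactly resumable (parameters, optimizer
moments, and RNG state round-trip bit for bit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .degradations import bicubic_resample
from .networks import (NetConfig, build_gde, build_gsr, build_discriminator,
                       to_tensor, to_images)
from .nn import AdamW, Module
from .objectives import (LossWeights, adversarial_d_loss, adversarial_g_loss,
                         identity_loss, weight_anchor_loss, cycle_loss,
                         total_de_loss, total_sr_loss, total_finetune_loss)

__all__ = [
    "StageConfig", "TrainState", "StagingError",
    "lr_at", "extract_patches", "augment_patch",
    "pretrain_gde", "train_stage_de", "train_stage_sr", "finetune_macular",
    "enhance", "save_checkpoint", "load_checkpoint", "make_pretrain_pairs",
]

STAGES = ("PRETRAIN", "DE", "SR", "FT")


class StagingError(RuntimeError):
    """A stage was invoked without the checkpoints of its prerequisites."""


@dataclass(frozen=True)
class StageConfig:
    """Optimizer, schedule, and patching settings for one training stage."""

    stage: str
    iterations: int = 500
    batch_size: int = 16
    patch_size: int = 128
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-2
    lr_halving_period: int = 200_000
    seed: int = 0
    frozen_groups: frozenset = field(default_factory=frozenset)
    macular_radius_frac: float = 0.25   # fallback macular radius, of min(H, W)
    critic_warmup: int = 200            # critic-only init steps before the loop
    critic_lr: float | None = None      # critic rate (None: same as lr)
    critic_interval: int = 1            # critic update every k-th iteration

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.patch_size % 4 != 0:
            raise ValueError("patch_size must be divisible by 4")
        defaults = {"PRETRAIN": frozenset(), "DE": frozenset({"encoder"}),
                    "SR": frozenset({"encoder", "decoder", "attention"}),
                    "FT": frozenset()}
        if not self.frozen_groups:
            object.__setattr__(self, "frozen_groups", defaults[self.stage])

    @staticmethod
    def tiny(stage: str, iterations: int | None = None, seed: int = 0,
             **kw) -> "StageConfig":
        """Desk-scale settings: batch 4, 64-pixel fundus patches.

        The adversarial stages initialize their critic for 200 steps at the
        base rate 1e-3 and then train the generator against it at a reduced
        rate (gradient noise at batch 4 is far higher than at the full-scale
        batch of 16; see the methods note). Fine-tuning runs 200 iterations.
        """
        kw.setdefault("batch_size", 4)
        kw.setdefault("patch_size", 64)
        if stage == "DE":
            kw.setdefault("lr", 1e-5)
        elif stage == "FT":
            kw.setdefault("lr", 2.5e-5)
        elif stage == "SR":
            kw.setdefault("lr", 1e-3)
        if stage in ("DE", "SR", "FT"):
            kw.setdefault("critic_lr", 1e-3)
            kw.setdefault("critic_interval", 10 ** 9)
        if iterations is None:
            iterations = 200 if stage == "FT" else 500
        return StageConfig(stage=stage, iterations=iterations, seed=seed, **kw)


@dataclass
class TrainState:
    """Everything needed to resume or audit a training run."""

    stage: str
    iteration: int
    models: dict                       # name -> Module
    optimizers: dict                   # name -> AdamW
    anchor: dict | None
    rng: np.random.Generator
    loss_history: list = field(default_factory=list)
    crop_log: list = field(default_factory=list)


def lr_at(iteration: int, base_lr: float, halving_period: int) -> float:
    """Step-decay schedule: the learning rate halves every `halving_period`."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return base_lr * 0.5 ** (iteration // halving_period)


# -- patch extraction ----------------------------------------------------------

def augment_patch(patch: np.ndarray, k_rot: int, flip_h: bool,
                  flip_v: bool) -> np.ndarray:
    """Apply a 90-degree rotation count and axis flips to an H x W x C patch."""
    out = np.rot90(patch, k_rot, axes=(0, 1))
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _sample_center(rng, H, W, p, region):
    lo_r, hi_r = p // 2, H - p + p // 2      # valid patch-center range
    lo_c, hi_c = p // 2, W - p + p // 2
    if region is None:
        r = int(rng.integers(lo_r, hi_r + 1))
        c = int(rng.integers(lo_c, hi_c + 1))
        return r, c
    (cy, cx), radius = region
    for _ in range(1000):
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform(0, 1))
        r = int(round(cy + rad * np.sin(ang)))
        c = int(round(cx + rad * np.cos(ang)))
        if lo_r <= r <= hi_r and lo_c <= c <= hi_c:
            return r, c
    return (int(np.clip(cy, lo_r, hi_r)), int(np.clip(cx, lo_c, hi_c)))


def extract_patches(img: np.ndarray, patch_size: int, n: int = 1,
                    region=None, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    augment: bool = False, centers_out: list | None = None
                    ) -> np.ndarray:
    """Seeded random crops, optionally restricted to a (center, radius) region.

    Returns an (n, patch_size, patch_size, 3) stack. With ``augment=True``
    each crop receives a random 90-degree rotation and horizontal/vertical
    flips. ``centers_out``, if given, collects the crop centers (for region
    audits).
    """
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape[:2]
    p = patch_size
    if H < p or W < p:
        raise ValueError(f"image {H}x{W} smaller than patch size {p}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty((n, p, p, img.shape[2]), dtype=np.float64)
    for i in range(n):
        r, c = _sample_center(rng, H, W, p, region)
        top, left = r - p // 2, c - p // 2
        patch = img[top:top + p, left:left + p]
        if centers_out is not None:
            centers_out.append((r, c))
        if augment:
            patch = augment_patch(patch, int(rng.integers(4)),
                                  bool(rng.integers(2)), bool(rng.integers(2)))
        out[i] = patch
    return out


def _sample_batch(images, patch_size, batch, rng, regions=None, augment=True,
                  centers_out=None):
    """Draw `batch` patches, each from a randomly chosen image."""
    out = np.empty((batch, patch_size, patch_size, 3))
    for b in range(batch):
        idx = int(rng.integers(len(images)))
        region = regions[idx] if regions is not None else None
        tmp: list = []
        out[b] = extract_patches(images[idx], patch_size, 1, region=region,
                                 rng=rng, augment=augment, centers_out=tmp)[0]
        if centers_out is not None:
            centers_out.append({"image": idx, "center": tmp[0],
                                "region": region})
    return out


def _as_image_list(source) -> list:
    """Accept a directory of images or a list/stack of arrays."""
    if isinstance(source, (str, Path)):
        from .interface import load_image
        paths = sorted(p for p in Path(source).iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif",
                                               ".tiff"} and
                       not p.name.startswith("mask_"))
        if not paths:
            raise IOError(f"no readable images in {source}")
        return [load_image(p) for p in paths]
    imgs = [np.asarray(im, dtype=np.float64) for im in source]
    if not imgs:
        raise ValueError("empty image collection")
    return imgs


# -- freezing and checkpoints --------------------------------------------------

def _apply_freezing(gde, frozen_groups) -> None:
    for gname, params in gde.parameter_groups().items():
        flag = gname not in frozen_groups
        for p in params.values():
            p.requires_grad = flag


def _anchored_params(gde, frozen_groups) -> dict:
    """Live (non-frozen) GDE parameters, keyed by name."""
    out = {}
    for gname, params in gde.parameter_groups().items():
        if gname not in frozen_groups:
            out.update(params)
    return out


def snapshot_params(model: Module) -> dict:
    return {k: p.data.copy() for k, p in model.named_parameters()}


def save_checkpoint(run_dir, stage: str, models: dict, optimizers=None,
                    iteration: int = 0, cfg: StageConfig | None = None,
                    rng: np.random.Generator | None = None,
                    anchor: dict | None = None) -> Path:
    """Serialize models (+ optimizer moments, RNG, anchor) under run_dir/stage."""
    stage_dir = Path(run_dir) / stage.lower()
    stage_dir.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for mname, model in models.items():
        for k, v in model.state_dict().items():
            arrays[f"{mname}/{k}"] = v
    if optimizers:
        for oname, opt in optimizers.items():
            for k, v in opt.state().items():
                arrays[f"opt/{oname}/{k}"] = v
    if anchor:
        for k, v in anchor.items():
            arrays[f"anchor/{k}"] = v
    path = stage_dir / "final.npz"
    np.savez(path, **arrays)
    sidecar = {
        "stage": stage,
        "iteration": int(iteration),
        "cfg": _jsonable(asdict(cfg)) if cfg is not None else None,
        "seed": cfg.seed if cfg is not None else None,
        "rng_state": rng.bit_generator.state if rng is not None else None,
        "models": sorted(models),
    }
    with open(stage_dir / "final.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_checkpoint(run_dir, stage: str):
    """Return (arrays, sidecar) for a stage, or raise :class:`StagingError`."""
    stage_dir = Path(run_dir) / stage.lower()
    npz, side = stage_dir / "final.npz", stage_dir / "final.json"
    if not npz.exists() or not side.exists():
        raise StagingError(
            f"stage {stage} requires a checkpoint under {stage_dir}, none found")
    with np.load(npz) as z:
        arrays = {k: z[k] for k in z.files}
    with open(side) as fh:
        sidecar = json.load(fh)
    return arrays, sidecar


def _restore_model(model: Module, arrays: dict, mname: str) -> None:
    state = {k[len(mname) + 1:]: v for k, v in arrays.items()
             if k.startswith(mname + "/")}
    model.load_state_dict(state)


def _restore_optimizer(opt: AdamW, arrays: dict, oname: str) -> None:
    state = {k[len("opt/" + oname) + 1:]: v for k, v in arrays.items()
             if k.startswith("opt/" + oname + "/")}
    if state:
        opt.load_state(state)


def _log_jsonl(path, record: dict) -> None:
    if path is None:
        return
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


# -- stage 0: supervised pretraining -------------------------------------------

def make_pretrain_pairs(params, n: int, chain=None, seed: int = 0) -> list:
    """Paired (degraded, clean-at-degraded-resolution) phantoms for pretraining.

    The clean target is the phantom downsampled to the degraded resolution,
    so the enhancer learns restoration at its working scale. This plays the
    role of initializing the enhancer on a retinal restoration corpus built
    from synthetic degradations; the adversarial stages never see pairings.
    ``chain=None`` uses the default UWF synthesis chain.
    """
    from .phantom import (PhantomParams, generate_phantom, synthesize_uwf,
                          default_uwf_chain)
    if not isinstance(params, PhantomParams):
        params = PhantomParams(**params)
    if chain is None:
        chain = default_uwf_chain()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    pairs = []
    for s in seeds:
        ph = generate_phantom(params, int(s))
        deg = synthesize_uwf(ph, chain, int(s) + 1)
        scale = deg.shape[0] / ph.clean.shape[0]
        target = (bicubic_resample(ph.clean, scale)
                  if scale != 1.0 else ph.clean.copy())
        pairs.append((deg, target))
    return pairs


def pretrain_gde(phantom_pairs, cfg: StageConfig,
                 net_cfg: NetConfig | None = None, gde=None,
                 run_dir=None, log_path=None):
    """Supervised MAE pretraining; returns (enhancer, anchor snapshot)."""
    if not phantom_pairs:
        raise ValueError("pretraining requires a nonempty dataset")
    net_cfg = net_cfg or NetConfig.tiny()
    if gde is None:
        gde = build_gde(net_cfg, seed=cfg.seed)
    gde.train()
    opt = AdamW(gde.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                eps=cfg.eps, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    for it in range(cfg.iterations):
        opt.lr = lr_at(it, cfg.lr, cfg.lr_halving_period)
        idx = rng.integers(len(phantom_pairs), size=cfg.batch_size)
        xs_list, ys_list = [], []
        for i in idx:
            deg, target = phantom_pairs[i]
            # rotation/flip augmentation, applied identically to both sides
            k_rot = int(rng.integers(4))
            fh, fv = bool(rng.integers(2)), bool(rng.integers(2))
            xs_list.append(augment_patch(deg, k_rot, fh, fv))
            ys_list.append(augment_patch(target, k_rot, fh, fv))
        xs, ys = np.stack(xs_list), np.stack(ys_list)
        gde.zero_grad()
        loss = (gde(to_tensor(xs)) - to_tensor(ys)).abs().mean()
        loss.backward()
        opt.step()
        _log_jsonl(log_path, {"iter": it, "stage": "PRETRAIN",
                              "recon": loss.item()})
    anchor = snapshot_params(gde)
    if run_dir is not None:
        save_checkpoint(run_dir, "PRETRAIN", {"gde": gde}, {"gde": opt},
                        cfg.iterations, cfg, rng, anchor=anchor)
    return gde, anchor


# -- stage DE: adversarial adaptation of the enhancer ---------------------------

def train_stage_de(uwf_source, fundus_source, gde, anchor,
                   cfg: StageConfig, net_cfg: NetConfig | None = None,
                   weights: LossWeights | None = None, dde=None,
                   run_dir=None, resume: bool = False,
                   log_path=None) -> TrainState:
    """Adapt the enhancer to the unpaired domains (encoder frozen)."""
    net_cfg = net_cfg or NetConfig.tiny()
    weights = weights or LossWeights()
    uwf = _as_image_list(uwf_source)
    fundus = _as_image_list(fundus_source)
    if dde is None:
        dde = build_discriminator(net_cfg, seed=cfg.seed + 101)

    _apply_freezing(gde, cfg.frozen_groups)
    # the enhancer adapts with its batch-norm statistics frozen: they were
    # estimated during pretraining on whole images, and re-estimating them
    # on small training crops skews full-image inference
    gde.eval()
    dde.train()
    g_opt = AdamW(gde.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    d_opt = AdamW(dde.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    start_it = 0
    if resume:
        arrays, sidecar = load_checkpoint(run_dir, "DE")
        _restore_model(gde, arrays, "gde")
        _restore_model(dde, arrays, "dde")
        _restore_optimizer(g_opt, arrays, "gde")
        _restore_optimizer(d_opt, arrays, "dde")
        rng.bit_generator.state = sidecar["rng_state"]
        start_it = sidecar["iteration"]

    anchor_live = _anchored_params(gde, cfg.frozen_groups)
    anchor_ref = {k: anchor[k] for k in anchor_live}
    state = TrainState("DE", start_it, {"gde": gde, "dde": dde},
                       {"gde": g_opt, "dde": d_opt}, anchor, rng)
    lowres_patch = max(4, cfg.patch_size // 4)

    if start_it == 0:
        # critic initialization: teach DDE to separate enhanced-UWF from
        # downsampled-fundus patches before any adversarial generator step
        d_opt.lr = cfg.critic_lr or cfg.lr
        for _ in range(cfg.critic_warmup):
            uwf_batch = _sample_batch(uwf, lowres_patch, cfg.batch_size, rng)
            fundus_batch = _sample_batch(fundus, cfg.patch_size,
                                         cfg.batch_size, rng)
            real_lr = np.stack([bicubic_resample(im, 0.25)
                                for im in fundus_batch])
            fake = gde(to_tensor(uwf_batch)).detach()
            d_loss = adversarial_d_loss(dde, to_tensor(real_lr), fake)
            dde.zero_grad()
            d_loss.backward()
            d_opt.step()
            dde.zero_grad()

    for it in range(start_it, cfg.iterations):
        g_opt.lr = lr_at(it, cfg.lr, cfg.lr_halving_period)
        d_opt.lr = lr_at(it, cfg.critic_lr or cfg.lr, cfg.lr_halving_period)
        uwf_batch = _sample_batch(uwf, lowres_patch, cfg.batch_size, rng)
        fundus_batch = _sample_batch(fundus, cfg.patch_size, cfg.batch_size, rng)
        real_lr = np.stack([bicubic_resample(im, 0.25) for im in fundus_batch])

        fake = gde(to_tensor(uwf_batch))
        d_loss = adversarial_d_loss(dde, to_tensor(real_lr), fake)

        if it % cfg.critic_interval == 0:
            gde.zero_grad(); dde.zero_grad()
            d_loss.backward()
            d_opt.step()

        # generator step against the just-updated critic; the enhancer's
        # forward graph is still valid (the critic step touched only DDE)
        gde.zero_grad(); dde.zero_grad()
        g_adv = adversarial_g_loss(dde, fake)
        ident = identity_loss(gde, uwf_batch)
        anch = weight_anchor_loss(anchor_live, anchor_ref)
        g_total = g_adv + weights.lambda_I * ident + weights.lambda_R * anch
        g_total.backward()
        g_opt.step()
        gde.zero_grad(); dde.zero_grad()

        bd = total_de_loss({"adv_g": g_adv, "adv_d": d_loss,
                            "identity": ident, "anchor": anch}, weights)
        state.loss_history.append(bd)
        state.iteration = it + 1
        _log_jsonl(log_path, {"iter": it, **bd.to_dict()})

    if run_dir is not None:
        save_checkpoint(run_dir, "DE", state.models, state.optimizers,
                        state.iteration, cfg, rng, anchor=anchor)
    return state


# -- stage SR: upscaler training with frozen enhancer ---------------------------

def train_stage_sr(uwf_source, fundus_source, gde, gsr,
                   cfg: StageConfig, net_cfg: NetConfig | None = None,
                   weights: LossWeights | None = None, dsr=None,
                   run_dir=None, resume: bool = False,
                   log_path=None) -> TrainState:
    """Train the x4 upscaler; every GDE parameter stays frozen."""
    net_cfg = net_cfg or NetConfig.tiny()
    weights = weights or LossWeights()
    uwf = _as_image_list(uwf_source)
    fundus = _as_image_list(fundus_source)
    if gde is None:
        if run_dir is None:
            raise StagingError("stage SR needs a trained enhancer "
                               "(run stage DE first)")
        arrays, _ = load_checkpoint(run_dir, "DE")
        gde = build_gde(net_cfg, seed=cfg.seed)
        _restore_model(gde, arrays, "gde")
    if gsr is None:
        gsr = build_gsr(net_cfg, seed=cfg.seed + 7)
    if dsr is None:
        dsr = build_discriminator(net_cfg, seed=cfg.seed + 202)

    # freeze the whole enhancer, including batch-norm statistics
    for p in gde.parameters():
        p.requires_grad = False
    gde.eval()
    gsr.train()
    dsr.train()
    g_opt = AdamW(gsr.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    d_opt = AdamW(dsr.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 2)
    start_it = 0
    if resume:
        arrays, sidecar = load_checkpoint(run_dir, "SR")
        _restore_model(gde, arrays, "gde")
        _restore_model(gsr, arrays, "gsr")
        _restore_model(dsr, arrays, "dsr")
        _restore_optimizer(g_opt, arrays, "gsr")
        _restore_optimizer(d_opt, arrays, "dsr")
        rng.bit_generator.state = sidecar["rng_state"]
        start_it = sidecar["iteration"]

    state = TrainState("SR", start_it, {"gde": gde, "gsr": gsr, "dsr": dsr},
                       {"gsr": g_opt, "dsr": d_opt}, None, rng)
    lowres_patch = max(4, cfg.patch_size // 4)

    if start_it == 0:
        # critic initialization against the untrained upscaler's outputs
        d_opt.lr = cfg.critic_lr or cfg.lr
        for _ in range(cfg.critic_warmup):
            uwf_batch = _sample_batch(uwf, lowres_patch, cfg.batch_size, rng)
            fundus_batch = _sample_batch(fundus, cfg.patch_size,
                                         cfg.batch_size, rng)
            fake_hr = gsr(gde(to_tensor(uwf_batch)).detach()).detach()
            d_loss = adversarial_d_loss(dsr, to_tensor(fundus_batch), fake_hr)
            dsr.zero_grad()
            d_loss.backward()
            d_opt.step()
            dsr.zero_grad()

    for it in range(start_it, cfg.iterations):
        g_opt.lr = lr_at(it, cfg.lr, cfg.lr_halving_period)
        d_opt.lr = lr_at(it, cfg.critic_lr or cfg.lr, cfg.lr_halving_period)
        uwf_batch = _sample_batch(uwf, lowres_patch, cfg.batch_size, rng)
        fundus_batch = _sample_batch(fundus, cfg.patch_size, cfg.batch_size, rng)

        enhanced = gde(to_tensor(uwf_batch)).detach()
        fake_hr = gsr(enhanced)
        d_loss = adversarial_d_loss(dsr, to_tensor(fundus_batch), fake_hr)

        if it % cfg.critic_interval == 0:
            gsr.zero_grad(); dsr.zero_grad()
            d_loss.backward()
            d_opt.step()

        gsr.zero_grad(); dsr.zero_grad()
        g_adv = adversarial_g_loss(dsr, fake_hr)
        cyc = cycle_loss(gsr, fundus_batch)
        g_total = g_adv + weights.lambda_C * cyc
        g_total.backward()
        g_opt.step()
        gsr.zero_grad(); dsr.zero_grad()

        bd = total_sr_loss({"adv_g": g_adv, "adv_d": d_loss, "cycle": cyc},
                           weights)
        state.loss_history.append(bd)
        state.iteration = it + 1
        _log_jsonl(log_path, {"iter": it, **bd.to_dict()})

    if run_dir is not None:
        save_checkpoint(run_dir, "SR", state.models, state.optimizers,
                        state.iteration, cfg, rng)
    return state


# -- macular fine-tuning ---------------------------------------------------------

def _macular_regions(images, centers, radius_frac):
    """Per-image (center, radius); default: central disk of radius_frac*min(H,W)."""
    regions = []
    for i, img in enumerate(images):
        H, W = img.shape[:2]
        if centers is not None and centers[i] is not None:
            cy, cx = centers[i]
            radius = min(H, W) / 6.0
        else:
            cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
            radius = radius_frac * min(H, W)
        regions.append(((float(cy), float(cx)), float(radius)))
    return regions


def finetune_macular(uwf_source, fundus_source, gde, gsr, dde, dsr,
                     anchor, cfg: StageConfig,
                     net_cfg: NetConfig | None = None,
                     weights: LossWeights | None = None,
                     macula_centers=None, uwf_macula_centers=None,
                     run_dir=None, log_path=None) -> TrainState:
    """Joint fine-tuning of both generators on macular-region patches."""
    net_cfg = net_cfg or NetConfig.tiny()
    weights = weights or LossWeights()
    uwf = _as_image_list(uwf_source)
    fundus = _as_image_list(fundus_source)
    if (gde is None or gsr is None or dde is None or dsr is None):
        if run_dir is None:
            raise StagingError("fine-tuning needs the DE and SR stage outputs")
        de_arrays, _ = load_checkpoint(run_dir, "DE")
        sr_arrays, _ = load_checkpoint(run_dir, "SR")
        gde = gde or build_gde(net_cfg, seed=cfg.seed)
        gsr = gsr or build_gsr(net_cfg, seed=cfg.seed + 7)
        dde = dde or build_discriminator(net_cfg, seed=cfg.seed + 101)
        dsr = dsr or build_discriminator(net_cfg, seed=cfg.seed + 202)
        _restore_model(gde, sr_arrays, "gde")
        _restore_model(dde, de_arrays, "dde")
        _restore_model(gsr, sr_arrays, "gsr")
        _restore_model(dsr, sr_arrays, "dsr")
        if anchor is None:
            anchor = {k[len("anchor/"):]: v for k, v in de_arrays.items()
                      if k.startswith("anchor/")}

    # nothing is frozen during fine-tuning; batch-norm runs on its frozen
    # running statistics (macular-only patches are a biased sample — letting
    # them re-estimate the statistics would skew full-image inference)
    for model in (gde, gsr, dde, dsr):
        for p in model.parameters():
            p.requires_grad = True
        model.eval()

    g_opt = AdamW(list(gde.named_parameters()) +
                  [("gsr." + n, p) for n, p in gsr.named_parameters()],
                  lr=cfg.lr, betas=cfg.betas, eps=cfg.eps,
                  weight_decay=cfg.weight_decay)
    dde_opt = AdamW(dde.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                    eps=cfg.eps, weight_decay=cfg.weight_decay)
    dsr_opt = AdamW(dsr.named_parameters(), lr=cfg.lr, betas=cfg.betas,
                    eps=cfg.eps, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 3)

    fundus_regions = _macular_regions(fundus, macula_centers,
                                      cfg.macular_radius_frac)
    uwf_regions = _macular_regions(uwf, uwf_macula_centers,
                                   cfg.macular_radius_frac)

    anchor_live = _anchored_params(gde, frozenset())
    anchor_ref = {k: anchor[k] for k in anchor_live} if anchor else None
    state = TrainState("FT", 0, {"gde": gde, "gsr": gsr, "dde": dde,
                                 "dsr": dsr},
                       {"g": g_opt, "dde": dde_opt, "dsr": dsr_opt},
                       anchor, rng)
    lowres_patch = max(4, cfg.patch_size // 4)

    for it in range(cfg.iterations):
        g_opt.lr = lr_at(it, cfg.lr, cfg.lr_halving_period)
        dde_opt.lr = dsr_opt.lr = lr_at(it, cfg.critic_lr or cfg.lr,
                                        cfg.lr_halving_period)
        uwf_crops, fundus_crops = [], []
        uwf_batch = _sample_batch(uwf, lowres_patch, cfg.batch_size, rng,
                                  regions=uwf_regions, centers_out=uwf_crops)
        fundus_batch = _sample_batch(fundus, cfg.patch_size, cfg.batch_size,
                                     rng, regions=fundus_regions,
                                     centers_out=fundus_crops)
        state.crop_log.append({"iter": it, "uwf": uwf_crops,
                               "fundus": fundus_crops})
        real_lr = np.stack([bicubic_resample(im, 0.25) for im in fundus_batch])

        enhanced = gde(to_tensor(uwf_batch))
        fake_hr = gsr(enhanced)
        de_d = adversarial_d_loss(dde, to_tensor(real_lr), enhanced)
        sr_d = adversarial_d_loss(dsr, to_tensor(fundus_batch), fake_hr)

        if it % cfg.critic_interval == 0:
            for m in (gde, gsr, dde, dsr):
                m.zero_grad()
            (de_d + sr_d).backward()
            dde_opt.step()
            dsr_opt.step()

        # joint generator step; the generator graphs are still valid
        # (the critic steps touched only DDE/DSR parameters)
        for m in (gde, gsr, dde, dsr):
            m.zero_grad()
        de_g = adversarial_g_loss(dde, enhanced)
        sr_g = adversarial_g_loss(dsr, fake_hr)
        ident = identity_loss(gde, uwf_batch)
        anch = (weight_anchor_loss(anchor_live, anchor_ref)
                if anchor_ref else None)
        cyc = cycle_loss(gsr, fundus_batch)
        g_total = de_g + weights.lambda_I * ident + sr_g \
            + weights.lambda_C * cyc
        if anch is not None:
            g_total = g_total + weights.lambda_R * anch
        g_total.backward()
        g_opt.step()
        for m in (gde, gsr, dde, dsr):
            m.zero_grad()

        de_bd = total_de_loss({"adv_g": de_g, "adv_d": de_d,
                               "identity": ident,
                               "anchor": anch if anch is not None else 0.0},
                              weights)
        sr_bd = total_sr_loss({"adv_g": sr_g, "adv_d": sr_d, "cycle": cyc},
                              weights)
        bd = total_finetune_loss(de_bd, sr_bd)
        state.loss_history.append(bd)
        state.iteration = it + 1
        _log_jsonl(log_path, {"iter": it, **bd.to_dict()})

    if run_dir is not None:
        save_checkpoint(run_dir, "FT", state.models, state.optimizers,
                        state.iteration, cfg, rng, anchor=anchor)
    return state


# -- inference -------------------------------------------------------------------

def enhance(image: np.ndarray, enhancer, upscaler, order: str = "de_sr",
            return_intermediate: bool = False):
    """Run the two-step pipeline on one image (values clipped to [0, 1]).

    ``order="de_sr"`` is the trained configuration: degradation enhancement
    first, then x4 super-resolution. ``order="sr_de"`` is the explicit
    ablation entry point that applies the upscaler first.
    """
    if order not in ("de_sr", "sr_de"):
        raise ValueError(f"order must be 'de_sr' or 'sr_de', got {order!r}")
    enhancer.eval()
    upscaler.eval()
    x = to_tensor(image)
    if order == "de_sr":
        inter = to_images(enhancer(x))[0]
        out = to_images(upscaler(to_tensor(inter)))[0]
    else:
        inter = to_images(upscaler(x))[0]
        out = to_images(enhancer(to_tensor(inter)))[0]
    if return_intermediate:
        return out, inter
    return out
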