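"""Synthetic retinal phantoms with known ground truth.

Real training corpora for unpaired UWF-to-fundus enhancement are private
clinical collections; this module generates stand-in scenes that reproduce
their *statistical* structure: an orange/red radial-gradient background with
low-frequency texture, a bright optic disc, dark curvilinear vessels growing
out of the disc as a seeded second-order random walk, a darker macular
region, and optionally small bright drusen deposits confined to the macula
(whose union is retained as a binary mask for evaluation only).

UWF-like counterparts are produced by a known degradation chain (blur,
uneven illumination, JPEG, x4 bicubic downsampling) plus seeded Gaussian
noise, so every degraded image has a recoverable clean source. Dataset
construction deliberately *unpairs* the two domains by permuting phantom
seeds between them, while a manifest records the hidden pairing for test
oracles (paired PSNR evaluation) — training code never reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .degradations import DegradationSpec, apply_chain

__all__ = [
    "PhantomParams",
    "Phantom",
    "generate_phantom",
    "synthesize_uwf",
    "build_unpaired_dataset",
    "default_uwf_chain",
]


def default_uwf_chain() -> list:
    """Default degradation chain for synthesizing UWF-like counterparts.

    The operator kinds follow the standard severe-degradation suite (blur,
    uneven illumination, JPEG, x4 bicubic downsampling) but blur support and
    compression are scaled to phantom resolution: a 7-pixel blur kernel on a
    ~100-pixel phantom would be proportionally far harsher than the optical
    blur of a real ultra-widefield capture, whose side runs to thousands of
    pixels. At phantom scale, sigma 3 and JPEG rate 0.5 leave the macular
    deposits attenuated but not erased — matching the clinical situation the
    pipeline targets (degraded but recoverable macular detail).
    """
    return [
        DegradationSpec("gaussian_blur", sigma=3.0),
        DegradationSpec("illumination", gamma=0.75),
        DegradationSpec("jpeg", rate=0.5),
        DegradationSpec("bicubic", scale=0.25),
    ]


@dataclass(frozen=True)
class PhantomParams:
    """Scene parameters for one synthetic retina.

    size
        Square side in pixels (>= 32).
    n_vessels
        Number of vessel random walks seeded at the optic disc.
    n_drusen
        Number of bright macular deposits (0 for a healthy retina).
    background_tint
        Base RGB of the fundus background, each channel in [0, 1].
    noise_sd
        Standard deviation of the Gaussian pixel noise added after the
        degradation chain when synthesizing the UWF-like counterpart.
    """

    size: int = 96
    n_vessels: int = 7
    n_drusen: int = 5
    background_tint: tuple = (0.82, 0.42, 0.22)
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.n_vessels < 0:
            raise ValueError(f"n_vessels must be >= 0, got {self.n_vessels}")
        if self.n_drusen < 0:
            raise ValueError(f"n_drusen must be >= 0, got {self.n_drusen}")
        if len(self.background_tint) != 3 or not all(
                0.0 <= t <= 1.0 for t in self.background_tint):
            raise ValueError(
                f"background_tint must be an RGB triple in [0,1], "
                f"got {self.background_tint}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class Phantom:
    """A clean fundus-quality scene plus its ground truth."""

    clean: np.ndarray          # H x W x 3 in [0, 1]
    drusen_mask: np.ndarray    # H x W bool
    macula_center: tuple       # (row, col)
    seed: int
    params: PhantomParams = field(default=None)


def _stamp_disk(img: np.ndarray, center, radius: float, soft: float = 1.0):
    """Return a [0,1] falloff map of a soft disk (1 inside, ->0 outside)."""
    H, W = img.shape[:2]
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip(1.0 - (d - radius) / max(soft, 1e-6), 0.0, 1.0) * (d < radius + soft)


def generate_phantom(params: PhantomParams, seed: int) -> Phantom:
    """Render one clean fundus-quality scene deterministically from (params, seed)."""
    if not isinstance(params, PhantomParams):
        params = PhantomParams(**params)
    rng = np.random.default_rng(seed)
    s = params.size
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0

    # (a) radial-gradient background with low-frequency texture
    r = np.hypot(rr - cy, cc - cx) / np.hypot(cy, cx)
    shade = 1.0 - 0.45 * r ** 2
    tint = np.asarray(params.background_tint, dtype=np.float64)
    img = shade[..., None] * tint[None, None, :]
    texture = rng.normal(0.0, 1.0, size=(s, s))
    texture = ndimage.gaussian_filter(texture, sigma=s / 16.0, mode="reflect")
    texture /= max(np.abs(texture).max(), 1e-9)
    img += 0.05 * texture[..., None] * tint[None, None, :]

    # (c) bright optic disc ellipse, displaced horizontally from center
    disc_c = (cy + rng.uniform(-0.05, 0.05) * s,
              cx - 0.30 * s + rng.uniform(-0.03, 0.03) * s)
    d = np.hypot((rr - disc_c[0]) / (0.085 * s), (cc - disc_c[1]) / (0.07 * s))
    disc = np.clip(1.0 - (d - 1.0) / 0.35, 0.0, 1.0) * (d < 1.35)
    disc_color = np.array([0.98, 0.85, 0.55])
    img = img * (1 - disc[..., None]) + disc[..., None] * disc_color

    # (d) darker macular disc, displaced to the other side
    mac = (int(round(cy + rng.uniform(-0.04, 0.04) * s)),
           int(round(cx + 0.18 * s + rng.uniform(-0.03, 0.03) * s)))
    mac = (int(np.clip(mac[0], 0, s - 1)), int(np.clip(mac[1], 0, s - 1)))
    mdist = np.hypot(rr - mac[0], cc - mac[1])
    mfall = np.exp(-0.5 * (mdist / (s / 9.0)) ** 2)
    img *= (1.0 - 0.28 * mfall[..., None])

    # (b) vessels: seeded second-order random walks from the disc region
    vessel = np.zeros((s, s))
    for _ in range(params.n_vessels):
        pos = np.array([disc_c[0] + rng.uniform(-2, 2),
                        disc_c[1] + rng.uniform(-2, 2)])
        ang = rng.uniform(0, 2 * np.pi)
        vel = np.array([np.sin(ang), np.cos(ang)])
        width = rng.uniform(0.8, 1.8) * s / 96.0
        n_steps = int(2.2 * s)
        for _step in range(n_steps):
            turn = rng.normal(0.0, 0.18)
            rot = np.array([[np.cos(turn), -np.sin(turn)],
                            [np.sin(turn), np.cos(turn)]])
            vel = rot @ vel
            pos = pos + vel
            if not (0 <= pos[0] < s and 0 <= pos[1] < s):
                break
            # Gaussian cross-section stamp on a small neighborhood
            i0, j0 = int(pos[0]), int(pos[1])
            half = max(2, int(3 * width))
            ii = np.arange(max(0, i0 - half), min(s, i0 + half + 1))
            jj = np.arange(max(0, j0 - half), min(s, j0 + half + 1))
            dd = ((ii[:, None] - pos[0]) ** 2 + (jj[None, :] - pos[1]) ** 2)
            vessel[np.ix_(ii, jj)] = np.maximum(
                vessel[np.ix_(ii, jj)], np.exp(-0.5 * dd / width ** 2))
    img *= (1.0 - 0.55 * vessel[..., None] * np.array([0.9, 1.0, 0.8]))

    # (e) drusen: small bright disks confined to the macular region
    mask = np.zeros((s, s), dtype=bool)
    mac_radius = s / 6.0
    for _ in range(params.n_drusen):
        ang = rng.uniform(0, 2 * np.pi)
        rad = mac_radius * np.sqrt(rng.uniform(0.0, 0.9))
        ctr = (mac[0] + rad * np.sin(ang), mac[1] + rad * np.cos(ang))
        radius = rng.uniform(1.0, 3.0)
        bright = rng.uniform(0.2, 0.4)
        fall = _stamp_disk(img, ctr, radius, soft=0.8)
        img += bright * fall[..., None]
        mask |= fall > 0.5

    clean = np.clip(img, 0.0, 1.0)
    return Phantom(clean=clean, drusen_mask=mask, macula_center=mac,
                   seed=int(seed), params=params)


def synthesize_uwf(phantom: Phantom, chain, seed: int) -> np.ndarray:
    """Degrade a phantom's clean image through `chain`, then add seeded noise."""
    if not chain:
        raise ValueError("degradation chain must be nonempty")
    out = apply_chain(phantom.clean, chain)
    if out.shape[0] < 8 or out.shape[1] < 8:
        raise ValueError(f"chain produced a sub-8-pixel image: {out.shape}")
    noise_sd = phantom.params.noise_sd if phantom.params is not None else 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def _unpair_permutation(n: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    if n >= 2 and np.array_equal(perm, np.arange(n)):
        perm = np.roll(perm, 1)
    return perm


def build_unpaired_dataset(params: PhantomParams, n: int, out_clean_dir,
                           out_uwf_dir, seed: int, chain=None) -> dict:
    """Write n clean and n UWF-like images as two *unpaired* domains.

    Clean image i comes from phantom i; UWF image j comes from phantom
    perm(j), so file index never pairs across domains. The returned (and
    saved) manifest records the hidden pairing — UWF file j matches clean
    file perm(j) — for evaluation oracles only. Drusen masks are written
    alongside the clean images.
    """
    from .interface import save_image, save_mask

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if chain is None:
        chain = default_uwf_chain()
    out_clean_dir, out_uwf_dir = Path(out_clean_dir), Path(out_uwf_dir)
    out_clean_dir.mkdir(parents=True, exist_ok=True)
    out_uwf_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    phantom_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    perm = _unpair_permutation(n, rng)

    phantoms = [generate_phantom(params, int(s)) for s in phantom_seeds]
    clean_files, uwf_files, mask_files = [], [], []
    for i, ph in enumerate(phantoms):
        cf = out_clean_dir / f"clean_{i:04d}.png"
        mf = out_clean_dir / f"mask_{i:04d}.png"
        save_image(ph.clean, cf)
        save_mask(ph.drusen_mask, mf)
        clean_files.append(cf.name)
        mask_files.append(mf.name)
    for j in range(n):
        ph = phantoms[int(perm[j])]
        uwf = synthesize_uwf(ph, chain, int(noise_seeds[j]))
        uf = out_uwf_dir / f"uwf_{j:04d}.png"
        save_image(uwf, uf)
        uwf_files.append(uf.name)

    manifest = {
        "clean_dir": str(out_clean_dir),
        "uwf_dir": str(out_uwf_dir),
        "clean_files": clean_files,
        "uwf_files": uwf_files,
        "masks": mask_files,
        "seeds": [int(s) for s in phantom_seeds],
        "noise_seeds": [int(s) for s in noise_seeds],
        "pairing": [int(p) for p in perm],   # uwf j  <->  clean pairing[j]
        "macula_centers": [list(map(int, ph.macula_center)) for ph in phantoms],
        "chain": [spec.to_dict() for spec in chain],
        "params": {
            "size": params.size, "n_vessels": params.n_vessels,
            "n_drusen": params.n_drusen,
            "background_tint": list(params.background_tint),
            "noise_sd": params.noise_sd,
        },
        "seed": int(seed),
    }
    with open(out_clean_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
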