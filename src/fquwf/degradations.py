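"""Parametrized image degradation operators.

Four operators model the corruption found in ultra-widefield (UWF) retinal
photographs relative to conventional fundus photographs: Gaussian blur,
uneven illumination via spatially varying gamma correction, JPEG compression,
and bicubic downsampling. Each maps an RGB image with values in [0, 1] to
another such image and is deterministic given its parameters.

Conventions chosen here (see docs/methods.md for rationale):

* ``gaussian_blur(sigma)`` uses a normalized Gaussian kernel whose *support*
  is sigma x sigma pixels (sigma rounded up to odd) with standard deviation
  sigma / 3, so the kernel decays close to zero at its border.
* ``gamma_illumination(gamma)`` raises each pixel to a spatially varying
  exponent that ramps smoothly (radial cosine) from 1.0 at the image center
  to ``gamma`` at the corners — gamma = 1 is the identity.
* ``jpeg_compress(rate)`` encodes at codec quality ``round(100 * rate)``.
* ``bicubic_resample(scale)`` resizes to ``round(H * scale), round(W * scale)``
  with the half-pixel-center bicubic convention of Pillow (antialiased when
  downsampling); ``scale = 1`` is the identity.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, asdict

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

__all__ = [
    "DegradationSpec",
    "gaussian_blur",
    "gamma_illumination",
    "jpeg_compress",
    "bicubic_resample",
    "apply_chain",
    "default_chain",
]

KINDS = ("gaussian_blur", "illumination", "jpeg", "bicubic")

#: Default parameter per operator kind (the standard severe-degradation suite).
DEFAULTS = {"sigma": 7.0, "gamma": 0.75, "rate": 0.25, "scale": 0.25}


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation operator and its parameter.

    Exactly the parameter matching ``kind`` is consulted; the others are
    ignored. ``None`` parameters fall back to :data:`DEFAULTS`.
    """

    kind: str
    sigma: float | None = None
    gamma: float | None = None
    rate: float | None = None
    scale: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def param(self) -> float:
        name = {"gaussian_blur": "sigma", "illumination": "gamma",
                "jpeg": "rate", "bicubic": "scale"}[self.kind]
        value = getattr(self, name)
        return DEFAULTS[name] if value is None else float(value)

    def apply(self, img: np.ndarray) -> np.ndarray:
        fn = {"gaussian_blur": gaussian_blur, "illumination": gamma_illumination,
              "jpeg": jpeg_compress, "bicubic": bicubic_resample}[self.kind]
        return fn(img, self.param)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return d

    @staticmethod
    def from_dict(d: dict) -> "DegradationSpec":
        allowed = {"kind", "sigma", "gamma", "rate", "scale"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown DegradationSpec fields: {sorted(unknown)}")
        return DegradationSpec(**d)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image array")
    return img


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Blur with a normalized Gaussian of support sigma x sigma (std sigma/3)."""
    if sigma is None or sigma < 1:
        raise ValueError(f"sigma must be >= 1, got {sigma}")
    img = _check_image(img)
    support = int(np.ceil(sigma))
    if support % 2 == 0:
        support += 1
    half = support // 2
    xs = np.arange(-half, half + 1, dtype=np.float64)
    std = sigma / 3.0
    k1 = np.exp(-0.5 * (xs / std) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndimage.convolve(img[..., c], kernel, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def gamma_illumination(img: np.ndarray, gamma: float) -> np.ndarray:
    """Spatially varying gamma: exponent 1 at center ramping to gamma at corners."""
    if gamma is None or gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    img = _check_image(img)
    if gamma == 1.0:
        return img.copy()
    H, W = img.shape[:2]
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = np.hypot(rr - cy, cc - cx) / np.hypot(cy, cx)
    g = 1.0 + (gamma - 1.0) * 0.5 * (1.0 - np.cos(np.pi * np.clip(r, 0, 1)))
    out = np.power(np.maximum(img, 0.0), g[..., None])
    return np.clip(out, 0.0, 1.0)


def jpeg_compress(img: np.ndarray, rate: float) -> np.ndarray:
    """Encode/decode through JPEG at quality round(100 * rate)."""
    if rate is None or not (0.0 < rate <= 1.0):
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    img = _check_image(img)
    quality = max(1, min(100, int(round(100 * rate))))
    u8 = (np.clip(img, 0, 1) * 255.0).round().astype(np.uint8)
    buf = _io.BytesIO()
    PILImage.fromarray(u8, mode="RGB").save(buf, format="JPEG", quality=quality)
    buf.seek(0)
    dec = np.asarray(PILImage.open(buf).convert("RGB"), dtype=np.float64) / 255.0
    return dec


def bicubic_resample(img: np.ndarray, scale: float) -> np.ndarray:
    """Bicubic resize by `scale` (antialiased when downsampling)."""
    if scale is None or scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    img = _check_image(img)
    if scale == 1.0:
        return img.copy()
    H, W = img.shape[:2]
    Hn, Wn = int(round(H * scale)), int(round(W * scale))
    if Hn < 8 or Wn < 8:
        raise ValueError(
            f"scale={scale} yields degenerate output size {Hn}x{Wn} (< 8 px)")
    out = np.empty((Hn, Wn, 3), dtype=np.float64)
    for c in range(3):
        ch = PILImage.fromarray(img[..., c].astype(np.float32), mode="F")
        out[..., c] = np.asarray(
            ch.resize((Wn, Hn), PILImage.Resampling.BICUBIC), dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


def apply_chain(img: np.ndarray, chain) -> np.ndarray:
    """Apply a sequence of :class:`DegradationSpec` in order."""
    if not chain:
        raise ValueError("degradation chain must be nonempty")
    out = _check_image(img)
    for spec in chain:
        out = spec.apply(out)
    return out


def default_chain() -> list[DegradationSpec]:
    """The four-operator severe-degradation chain at its default parameters:
    blur (sigma 7) -> uneven illumination (gamma 0.75) -> JPEG (rate 0.25)
    -> bicubic downsampling (scale 0.25)."""
    return [
        DegradationSpec("gaussian_blur", sigma=7.0),
        DegradationSpec("illumination", gamma=0.75),
        DegradationSpec("jpeg", rate=0.25),
        DegradationSpec("bicubic", scale=0.25),
    ]
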