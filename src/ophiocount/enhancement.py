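"""Underwater-image enhancement pre-processing via a named registry.

Enhancement is applied to the whole mosaic before patching.  Three
operators are built in: gamma intensity correction (``gc``), contrast
limited adaptive histogram equalization (``clahe``) and a simple global
per-channel percentile stretch (``stretch``).  Further methods can be
registered by name without touching the callers.  All operators map
[0, 1] images to [0, 1] images of identical shape, deterministically;
``none`` is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage import color
from skimage.exposure import equalize_adapthist


@dataclass(frozen=True)
class EnhancementSpec:
    """A registered operator name plus its keyword parameters."""

    name: str = "none"
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "EnhancementSpec":
        return cls(name=d.get("name", "none"), params=dict(d.get("params", {})))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("enhancement expects intensities in [0, 1]")
    return image


def gamma_correct(image: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Per-channel power law ``out = in ** gamma``; gamma must be > 0."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return np.power(_check_image(image), gamma)


def clahe(
    image: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Tile-wise clipped histogram equalization of the luminance channel.

    RGB input is equalized in luminance (CIELAB L) with chroma
    preserved; grayscale input is equalized directly.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if tile_grid[0] <= 0 or tile_grid[1] <= 0:
        raise ValueError("tile_grid must be positive")
    image = _check_image(image)
    if image.ndim == 2:
        return np.clip(
            equalize_adapthist(image, kernel_size=tile_grid, clip_limit=clip_limit),
            0.0,
            1.0,
        )
    lab = color.rgb2lab(image)
    lum = lab[:, :, 0] / 100.0
    lab[:, :, 0] = (
        equalize_adapthist(lum, kernel_size=tile_grid, clip_limit=clip_limit) * 100.0
    )
    return np.clip(color.lab2rgb(lab), 0.0, 1.0)


def percentile_stretch(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Global linear stretch mapping each channel's percentiles to [0, 1].

    A flat channel (equal percentiles) is passed through unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got {(low_pct, high_pct)}")
    image = _check_image(image)
    single = image.ndim == 2
    img = image[:, :, None] if single else image
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        lo, hi = np.percentile(img[:, :, ch], [low_pct, high_pct])
        if hi <= lo:
            out[:, :, ch] = img[:, :, ch]
        else:
            out[:, :, ch] = np.clip((img[:, :, ch] - lo) / (hi - lo), 0.0, 1.0)
    return out[:, :, 0] if single else out


_REGISTRY: dict[str, Callable[..., np.ndarray]] = {
    "none": lambda image: _check_image(image),
    "gc": gamma_correct,
    "clahe": clahe,
    "stretch": percentile_stretch,
}


def register(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register an enhancement operator under a new name."""
    _REGISTRY[name] = fn


def available() -> list[str]:
    return sorted(_REGISTRY)


def apply_enhancement(image: np.ndarray, spec: EnhancementSpec) -> np.ndarray:
    """Dispatch to the registered operator named by the spec."""
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown enhancement {spec.name!r}; registered: {available()}"
        )
    return _REGISTRY[spec.name](image, **spec.params)
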