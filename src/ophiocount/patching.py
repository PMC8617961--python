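"""Sliding-window tiling of mosaics and reassembly of patch predictions.

Large seabed mosaics do not fit a fixed-size network input, so they are
block-processed: tiled into overlapping ``patch_size`` squares at a
given ``stride`` (defaults 288/144), predicted per patch and stitched
back.  The grid places offsets at stride multiples plus, when the last
strided position falls short of the border, a final flush offset at
``dim - patch_size`` so every pixel is covered without padding.
Overlapping predictions merge by arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_PATCH_SIZE = 288
DEFAULT_STRIDE = 144


@dataclass(frozen=True)
class PatchGrid:
    """Deterministic set of patch offsets tiling an image."""

    patch_size: int
    stride: int
    offsets: tuple[tuple[int, int], ...]
    image_height: int
    image_width: int

    def __len__(self) -> int:
        return len(self.offsets)


def _axis_offsets(dim: int, patch_size: int, stride: int) -> list[int]:
    last = dim - patch_size
    offs = list(range(0, last + 1, stride))
    if offs[-1] != last:
        offs.append(last)  # flush-edge offset guarantees full coverage
    return offs


def plan_grid(
    height: int,
    width: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> PatchGrid:
    """Plan the row-major patch grid covering an image completely."""
    if patch_size > height or patch_size > width:
        raise ValueError(
            f"image {height}x{width} smaller than patch {patch_size}; pad first"
        )
    if not (1 <= stride <= patch_size):
        raise ValueError(f"stride must be in [1, patch_size], got {stride}")
    rows = _axis_offsets(height, patch_size, stride)
    cols = _axis_offsets(width, patch_size, stride)
    offsets = tuple((r, c) for r in rows for c in cols)
    return PatchGrid(patch_size, stride, offsets, height, width)


def slice_patches(image: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Crop the image at every grid offset, in offset order."""
    if image.shape[:2] != (grid.image_height, grid.image_width):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match grid "
            f"({grid.image_height}, {grid.image_width})"
        )
    p = grid.patch_size
    return [image[r : r + p, c : c + p] for r, c in grid.offsets]


def reassemble(prob_patches: list[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Mean-merge per-patch probability maps into a mosaic-sized map."""
    if len(prob_patches) != len(grid.offsets):
        raise ValueError(
            f"got {len(prob_patches)} patches for {len(grid.offsets)} offsets"
        )
    p = grid.patch_size
    acc = np.zeros((grid.image_height, grid.image_width), dtype=np.float64)
    cover = np.zeros_like(acc)
    for patch, (r, c) in zip(prob_patches, grid.offsets):
        if patch.shape[:2] != (p, p):
            raise ValueError(f"patch shape {patch.shape} != ({p}, {p})")
        acc[r : r + p, c : c + p] += patch
        cover[r : r + p, c : c + p] += 1.0
    return (acc / cover).astype(np.float32)
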