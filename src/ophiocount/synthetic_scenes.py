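"""Synthetic seabed scenes with known brittle-star ground truth.

Generates reproducible mosaic-like images in which each organism is a
filled elliptical body disc with (by default five) tapering, gently
curved arms radiating outward, placed on a low-frequency textured
background with additive Gaussian noise.  Every scene carries exact
ground truth in both annotation variants (``full`` and ``disc``), so the
whole segment-and-count pipeline is testable without any real imagery.

Stitching-style artifacts seen in real video mosaics can be emulated via
flags: organisms clipped at the mosaic border, a duplicated (doubly
rendered) organism, and an organism whose central disc is hidden in the
imagery while its arms remain visible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import disk as _draw_disk

from .annotations import AnnotationSet, PolygonAnnotation, rasterize, trace_mask


class PlacementError(RuntimeError):
    """Raised when the requested number of organisms cannot be placed."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    Sizes are in pixels, intensities dimensionless in [0, 1].  The
    defaults place well-separated organisms whose discs comfortably pass
    the 40 px minimal-area filter and the 55 px marker-separation rule
    of the counting workflow, so that counting the ground-truth disc
    mask recovers the true organism count exactly.
    """

    width: int = 640
    height: int = 640
    n_stars: int | tuple[int, int] = (15, 40)
    disc_radius_range: tuple[float, float] = (5.0, 9.0)
    n_arms: int = 5
    arm_length_range: tuple[float, float] = (14.0, 28.0)
    arm_width_range: tuple[float, float] = (2.0, 3.5)
    organism_intensity: float = 0.25
    background_mean: float = 0.55
    background_texture_scale: float = 0.06
    noise_sd: float = 0.03
    clip_at_border: bool = False
    duplicate_instance: bool = False
    hide_disc: bool = False
    min_center_separation: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        for name in ("disc_radius_range", "arm_length_range", "arm_width_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        if isinstance(self.n_stars, tuple):
            lo, hi = self.n_stars
            if not (0 <= lo <= hi):
                raise ValueError(f"n_stars range invalid: {self.n_stars}")
        elif self.n_stars < 0:
            raise ValueError("n_stars must be >= 0")
        if self.n_arms < 0:
            raise ValueError("n_arms must be >= 0")

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in ("n_stars", "disc_radius_range", "arm_length_range", "arm_width_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Scene:
    """One synthetic mosaic with exact ground truth."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    annotations_full: AnnotationSet
    annotations_disc: AnnotationSet
    true_count: int
    seed: int
    mask_full: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    mask_disc: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _quadratic_bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _render_arm(canvas: np.ndarray, origin, angle, length, width, curl, rng) -> None:
    """Stamp a tapering curved arm onto a boolean canvas.

    The arm is a quadratic Bezier from the disc edge outward, its
    control point offset sideways to bend it; thickness tapers linearly
    from ``width`` at the base to ~1 px at the tip.
    """
    h, w = canvas.shape
    direction = np.array([np.cos(angle), np.sin(angle)])
    normal = np.array([-direction[1], direction[0]])
    p0 = np.asarray(origin, dtype=float)
    p2 = p0 + direction * length
    p1 = p0 + direction * (0.5 * length) + normal * curl * length
    n = max(int(2 * length), 8)
    points = _quadratic_bezier(p0, p1, p2, n)
    radii = np.linspace(max(width / 2.0, 0.6), 0.6, n)
    for (x, y), r in zip(points, radii):
        rr, cc = _draw_disk((y, x), max(r, 0.6), shape=(h, w))
        canvas[rr, cc] = True


def _render_organism(shape, center, rng, cfg: SceneConfig):
    """Render one organism; returns (full_mask, disc_mask) boolean arrays."""
    h, w = shape
    disc = np.zeros(shape, dtype=bool)
    full = np.zeros(shape, dtype=bool)
    r = rng.uniform(*cfg.disc_radius_range)
    ecc = rng.uniform(0.75, 1.0)  # mild eccentricity
    orient = rng.uniform(0, np.pi)
    rr, cc = _draw_ellipse(center[1], center[0], r, r * ecc, shape=shape, rotation=orient)
    disc[rr, cc] = True

    base_angle = rng.uniform(0, 2 * np.pi)
    for k in range(cfg.n_arms):
        angle = base_angle + 2 * np.pi * k / max(cfg.n_arms, 1) + rng.normal(0, 0.12)
        length = rng.uniform(*cfg.arm_length_range)
        width = rng.uniform(*cfg.arm_width_range)
        curl = rng.uniform(-0.18, 0.18)
        # start slightly inside the disc so the arm is connected to it
        origin = np.asarray(center, dtype=float) + 0.6 * r * np.array(
            [np.cos(angle), np.sin(angle)]
        )
        _render_arm(full, origin, angle, length, width, curl, rng)
    full |= disc
    # fill any pin-holes so each instance is a solid region whose traced
    # contour rasterizes back to the identical mask
    full = binary_fill_holes(full)
    disc = binary_fill_holes(disc)
    return full, disc


def _canonicalize(
    mask: np.ndarray, variant: str, annotator: str = "synthetic"
) -> tuple[PolygonAnnotation | None, np.ndarray]:
    """Trace the largest contour and re-rasterize it as the canonical mask.

    The returned mask is exactly the rasterization of the returned
    polygon, so ``rasterize(annotations) == scene mask`` holds by
    construction.  Stray pixels attached only diagonally (which the
    contour tracer separates) are dropped from the canonical shape.
    """
    contours = trace_mask(mask)
    if not contours:
        return None, np.zeros_like(mask)
    longest = max(contours, key=len)
    poly = PolygonAnnotation(vertices=longest, variant=variant, annotator=annotator)
    return poly, poly.mask(*mask.shape)


def _resolve_n_stars(cfg: SceneConfig, rng) -> int:
    if isinstance(cfg.n_stars, tuple):
        lo, hi = cfg.n_stars
        return int(rng.integers(lo, hi + 1))
    return int(cfg.n_stars)


def _place_centers(cfg: SceneConfig, n: int, rng) -> list[np.ndarray]:
    """Rejection-sample organism centres honouring the separation rule."""
    margin = cfg.disc_radius_range[1] + cfg.arm_length_range[1]
    lo_x, hi_x = margin, cfg.width - margin
    lo_y, hi_y = margin, cfg.height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        # scene smaller than one organism footprint: allow anywhere
        lo_x, hi_x, lo_y, hi_y = 0, cfg.width, 0, cfg.height
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 300 * max(n, 1)
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} organisms with separation "
                f"{cfg.min_center_separation} in a {cfg.width}x{cfg.height} scene "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if all(
            np.hypot(*(cand - c)) >= cfg.min_center_separation for c in centers
        ):
            centers.append(cand)
    if cfg.clip_at_border and centers:
        # push one organism half out of the frame to emulate mosaic clipping
        centers[0] = np.array([0.0, centers[0][1]])
    return centers


def _background(cfg: SceneConfig, rng) -> np.ndarray:
    h, w = cfg.height, cfg.width
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=18.0)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * cfg.background_texture_scale
    return cfg.background_mean + texture


# per-channel tints giving the greenish cast of shallow-water imagery
_BG_TINT = np.array([0.82, 1.00, 0.96])
_ORG_TINT = np.array([1.00, 0.92, 0.84])


def generate_scene(config: SceneConfig, seed: int | None = None) -> Scene:
    """Generate one scene; identical (config, seed) gives identical output.

    Raises :class:`PlacementError` (never a silent undercount) when the
    requested organism count cannot be placed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = _resolve_n_stars(config, rng)
    centers = _place_centers(config, n, rng)

    shape = (config.height, config.width)
    scene_full = np.zeros(shape, dtype=bool)
    scene_disc = np.zeros(shape, dtype=bool)
    full_polys: list[PolygonAnnotation] = []
    disc_polys: list[PolygonAnnotation] = []

    hide_idx = int(rng.integers(0, n)) if (config.hide_disc and n > 0) else -1
    dup_idx = int(rng.integers(0, n)) if (config.duplicate_instance and n > 0) else -1

    for i, center in enumerate(centers):
        full, disc = _render_organism(shape, center, rng, config)
        if i == hide_idx:
            # disc hidden in the imagery: arms only, no disc annotation
            arms_only = full & ~disc
            arms_only = binary_fill_holes(arms_only)
            full, disc = arms_only, np.zeros(shape, dtype=bool)
        if i == dup_idx:
            # stitching artifact: the organism appears twice, counted once
            offset = rng.uniform(6, 12) * np.array(
                [np.cos(a := rng.uniform(0, 2 * np.pi)), np.sin(a)]
            )
            ghost_full, ghost_disc = _render_organism(shape, center + offset, rng, config)
            for ghost, target, polys, variant in (
                (ghost_full, scene_full, full_polys, "full"),
                (ghost_disc, scene_disc, disc_polys, "disc"),
            ):
                poly, canon = _canonicalize(ghost, variant)
                target |= canon
                if poly is not None:
                    polys.append(poly)
        poly, full_canon = _canonicalize(full, "full")
        dpoly, disc_canon = _canonicalize(disc, "disc")
        if poly is None:
            continue
        scene_full |= full_canon
        scene_disc |= disc_canon
        full_polys.append(poly)
        if dpoly is not None:
            disc_polys.append(dpoly)

    image_gray = _background(config, rng)
    image_gray[scene_full] = config.organism_intensity
    image = image_gray[:, :, None] * np.where(
        scene_full[:, :, None], _ORG_TINT, _BG_TINT
    )
    image += rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    mosaic_id = f"synthetic-{seed}"
    return Scene(
        image=image,
        annotations_full=AnnotationSet(mosaic_id, "full", "synthetic", full_polys),
        annotations_disc=AnnotationSet(mosaic_id, "disc", "synthetic", disc_polys),
        true_count=n,
        seed=seed,
        mask_full=scene_full,
        mask_disc=scene_disc,
    )


def generate_dataset(config: SceneConfig, n_scenes: int, seed: int) -> list[Scene]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from ``seed``."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    return [generate_scene(config, int(s)) for s in scene_seeds]


def write_scene(scene: Scene, out_dir: str | Path, stem: str | None = None,
                config: SceneConfig | None = None) -> dict:
    """Write a scene as PNG image + annotation JSONs + manifest JSON."""
    from PIL import Image

    from .annotations import write_annotations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or f"scene_{scene.seed}"
    img8 = (np.clip(scene.image, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(img8).save(out / f"{stem}.png")
    write_annotations(scene.annotations_full, out / f"{stem}.full.json")
    write_annotations(scene.annotations_disc, out / f"{stem}.disc.json")
    manifest = {
        "stem": stem,
        "seed": scene.seed,
        "true_count": scene.true_count,
        "config": config.to_dict() if config is not None else None,
    }
    (out / f"{stem}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
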