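"""Polygon annotations of benthic organisms and their rasterization.

Annotations follow the field-survey convention of closed polygons drawn
around each visible organism, in one of two marker variants: ``full``
(the whole star-like outline, arms included) or ``disc`` (the central
body disc only).  An :class:`AnnotationSet` collects the polygons of one
mosaic, one variant and one annotator.

Coordinates are 0-based pixel centres, ``x`` rightward and ``y``
downward.  A pixel belongs to a rasterized polygon when its centre lies
inside or on the polygon boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import polygon as _draw_polygon

VARIANTS = ("full", "disc")


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file or object violates the schema."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """A single closed polygon around one organism instance."""

    vertices: tuple[tuple[float, float], ...]
    label: str = "brittle_star"
    variant: str = "full"
    annotator: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise AnnotationSchemaError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        if self.variant not in VARIANTS:
            raise AnnotationSchemaError(f"unknown variant {self.variant!r}")
        arr = np.asarray(self.vertices, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise AnnotationSchemaError("polygon vertices must be finite")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    @property
    def xy(self) -> np.ndarray:
        """Vertices as an (n, 2) float array of (x, y)."""
        return np.asarray(self.vertices, dtype=float)

    def centroid(self) -> tuple[float, float]:
        """Mean of the vertices; adequate for instance assignment rules."""
        arr = self.xy
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def mask(self, height: int, width: int) -> np.ndarray:
        """Rasterize this polygon alone into a boolean (height, width) mask."""
        return _rasterize_polygons([self], height, width)

    def area(self, height: int, width: int) -> int:
        """Rasterized pixel area within the given frame."""
        return int(self.mask(height, width).sum())


@dataclass
class AnnotationSet:
    """All polygons of one mosaic in one marker variant by one annotator."""

    mosaic_id: str
    variant: str
    annotator: str
    polygons: list[PolygonAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise AnnotationSchemaError(f"unknown variant {self.variant!r}")
        for i, poly in enumerate(self.polygons):
            if poly.variant != self.variant:
                raise AnnotationSchemaError(
                    f"polygon {i} has variant {poly.variant!r}, set is {self.variant!r}"
                )

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self):
        return iter(self.polygons)


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write an annotation set as JSON (schema documented in the README)."""
    payload = {
        "mosaic_id": aset.mosaic_id,
        "variant": aset.variant,
        "annotator": aset.annotator,
        "polygons": [
            {"label": p.label, "vertices": [[x, y] for x, y in p.vertices]}
            for p in aset.polygons
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read and validate an annotation set from JSON.

    Raises :class:`AnnotationSchemaError` naming the offending polygon
    index on any schema violation.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("mosaic_id", "variant", "annotator", "polygons"):
        if key not in payload:
            raise AnnotationSchemaError(f"missing key {key!r} in {path}")
    variant = payload["variant"]
    if variant not in VARIANTS:
        raise AnnotationSchemaError(f"unknown variant {variant!r} in {path}")
    polygons = []
    for i, entry in enumerate(payload["polygons"]):
        verts = entry.get("vertices", [])
        try:
            poly = PolygonAnnotation(
                vertices=tuple((v[0], v[1]) for v in verts),
                label=entry.get("label", "brittle_star"),
                variant=variant,
                annotator=payload["annotator"],
            )
        except (AnnotationSchemaError, TypeError, IndexError) as exc:
            raise AnnotationSchemaError(f"polygon {i}: {exc}") from exc
        polygons.append(poly)
    return AnnotationSet(
        mosaic_id=payload["mosaic_id"],
        variant=variant,
        annotator=payload["annotator"],
        polygons=polygons,
    )


def _rasterize_polygons(
    polygons: Iterable[PolygonAnnotation], height: int, width: int
) -> np.ndarray:
    # Rasterize into a 1-px padded canvas so vertices slightly outside the
    # frame (clipped organisms, half-integer traced contours) fill correctly,
    # then crop back.
    mask = np.zeros((height + 2, width + 2), dtype=bool)
    for poly in polygons:
        arr = poly.xy
        rr, cc = _draw_polygon(arr[:, 1] + 1.0, arr[:, 0] + 1.0, shape=mask.shape)
        mask[rr, cc] = True
    return mask[1:-1, 1:-1]


def rasterize(aset: AnnotationSet | Sequence[PolygonAnnotation], height: int, width: int) -> np.ndarray:
    """Union of the filled polygons as a boolean (height, width) mask.

    Overlapping polygons merge without error; the union is order
    independent and idempotent.
    """
    polys = aset.polygons if isinstance(aset, AnnotationSet) else list(aset)
    return _rasterize_polygons(polys, height, width)


def trace_mask(mask: np.ndarray) -> list[tuple[tuple[float, float], ...]]:
    """Trace the outer contour(s) of a boolean mask as (x, y) polygons.

    Contours run between pixel centres at half-integer coordinates (the
    0.5 level of the padded mask), so rasterizing a traced contour with
    the pixel-centre rule reproduces the original solid region exactly.
    """
    from skimage.measure import find_contours

    padded = np.pad(mask.astype(float), 1)
    out = []
    for contour in find_contours(padded, 0.5):
        # (row, col) in padded frame -> (x, y) in image frame
        xy = tuple((float(c - 1.0), float(r - 1.0)) for r, c in contour)
        if len(xy) >= 3:
            out.append(xy)
    return out
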