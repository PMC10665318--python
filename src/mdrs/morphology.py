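"""Per-particle shape, size and transparency descriptors.

Definitions (all dimensionless descriptors lie in (0, 1] up to a small
discretisation allowance):

- ECD: equivalent circular diameter, ``2*sqrt(area/pi)``.
- length / feret_max: maximum distance between two parallel tangents.
- aspect ratio: min Feret / max Feret (width over height).
- circularity: perimeter of the equal-area circle over the actual
  perimeter, ``2*sqrt(pi*area)/perimeter``.  The squared variant
  ``4*pi*area/perimeter**2`` used by some flow-imaging instruments is
  reported alongside as ``circularity_hs`` for cross-tool comparison.
- convexity: convex-hull perimeter over the actual perimeter.
- elongation: ``1 - aspect ratio``, exactly.
- mean intensity: average original gray level inside the filled mask; a
  transparency proxy (higher = more transparent on a bright field).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry

#: discretisation allowance on descriptors bounded by 1
EPSILON = 0.02


def aspect_ratio(feret_min: float, feret_max: float) -> float:
    if feret_max <= 0 or feret_min <= 0:
        raise ValueError("Feret diameters must be positive")
    if feret_min > feret_max * (1 + 1e-9):
        raise ValueError("feret_min exceeds feret_max")
    return feret_min / feret_max


def elongation(aspect: float) -> float:
    """Elongation is one minus the aspect ratio."""
    return 1.0 - aspect


def circularity(area: float, perimeter: float) -> float:
    """Equal-area-circle circumference over the actual perimeter."""
    if perimeter <= 0 or area <= 0:
        raise ValueError("area and perimeter must be positive")
    return 2.0 * np.sqrt(np.pi * area) / perimeter


def circularity_hs(area: float, perimeter: float) -> float:
    """Squared ('high-sensitivity') circularity, 4*pi*A/P^2."""
    return circularity(area, perimeter) ** 2


def convexity(hull_perimeter: float, perimeter: float) -> float:
    if perimeter <= 0 or hull_perimeter <= 0:
        raise ValueError("perimeters must be positive")
    if hull_perimeter > perimeter * (1 + EPSILON):
        raise ValueError("hull perimeter exceeds particle perimeter")
    return hull_perimeter / perimeter


def shape_factors(
    area: float,
    perimeter: float,
    feret_min: float,
    feret_max: float,
    hull_perimeter: float,
) -> tuple[float, float, float, float]:
    """(aspect_ratio, circularity, convexity, elongation) from raw measures."""
    a = aspect_ratio(feret_min, feret_max)
    return (
        a,
        circularity(area, perimeter),
        convexity(hull_perimeter, perimeter),
        elongation(a),
    )


@dataclass(frozen=True)
class MorphologyRecord:
    """All descriptors for one particle; lengths in micrometres."""

    particle_id: int
    area: float
    perimeter: float
    ecd: float
    feret_max: float
    feret_min: float
    aspect_ratio: float
    circularity: float
    circularity_hs: float
    convexity: float
    elongation: float
    mean_intensity: float


def _contour_of(region_or_contour) -> np.ndarray:
    contour = getattr(region_or_contour, "contour", region_or_contour)
    return geometry.as_polygon(contour)


def measure_area_perimeter(region_or_contour, pixel_size: float) -> tuple[float, float]:
    """Silhouette area (um^2) and boundary length (um) of the sub-pixel contour."""
    v = _contour_of(region_or_contour)
    if not geometry.is_simple_polygon(v):
        raise ValueError("contour is self-intersecting or degenerate")
    area = geometry.polygon_area(v) * pixel_size ** 2
    perim = geometry.polygon_perimeter(v) * pixel_size
    return area, perim


def feret_diameters(region_or_contour, pixel_size: float) -> tuple[float, float]:
    """(feret_min, feret_max) in micrometres, exact on the convex hull."""
    v = _contour_of(region_or_contour)
    fmin, fmax = geometry.feret_diameters(v)
    return fmin * pixel_size, fmax * pixel_size


def mean_intensity(region, image) -> float:
    """Mean original gray level over the region's filled mask."""
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    local = pixels[region.slices][region.mask_local]
    if local.size == 0:
        raise ValueError("empty mask")
    return float(local.mean())


def measure_polygon(
    polygon,
    particle_id: int = -1,
    mean_intensity: float = float("nan"),
) -> MorphologyRecord:
    """Descriptors of a continuous polygon (coordinates already in um).

    Used for phantom ground truth: the descriptors come from the generating
    polygon itself, never from a raster.
    """
    v = geometry.as_polygon(polygon)
    area = geometry.polygon_area(v)
    perim = geometry.polygon_perimeter(v)
    fmin, fmax = geometry.feret_diameters(v)
    hp = geometry.hull_perimeter(v)
    # a convex-hull perimeter can exceed a nearly-convex polygon's perimeter
    # by floating-point slack only; clamp that slack
    hp = min(hp, perim)
    a, c, cx, e = shape_factors(area, perim, fmin, fmax, hp)
    return MorphologyRecord(
        particle_id=particle_id,
        area=area,
        perimeter=perim,
        ecd=geometry.ecd_from_area(area),
        feret_max=fmax,
        feret_min=fmin,
        aspect_ratio=a,
        circularity=c,
        circularity_hs=circularity_hs(area, perim),
        convexity=cx,
        elongation=e,
        mean_intensity=mean_intensity,
    )


def measure_region(region, image, pixel_size: float | None = None) -> MorphologyRecord:
    """Descriptors of a segmented region measured on its sub-pixel contour."""
    if pixel_size is None:
        pixel_size = image.pixel_size
    area, perim = measure_area_perimeter(region, pixel_size)
    fmin, fmax = feret_diameters(region, pixel_size)
    hp = min(geometry.hull_perimeter(_contour_of(region)) * pixel_size, perim)
    a, c, cx, e = shape_factors(area, perim, fmin, fmax, hp)
    return MorphologyRecord(
        particle_id=region.id,
        area=area,
        perimeter=perim,
        ecd=geometry.ecd_from_area(area),
        feret_max=fmax,
        feret_min=fmin,
        aspect_ratio=a,
        circularity=c,
        circularity_hs=circularity_hs(area, perim),
        convexity=cx,
        elongation=e,
        mean_intensity=mean_intensity(region, image),
    )


def records_to_frame(records: Iterable[MorphologyRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(MorphologyRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def summarize(records: Sequence[MorphologyRecord], decimals: int = 2) -> pd.DataFrame:
    """Mean +/- SD table over all records, rounded to reporting precision."""
    df = records_to_frame(records).drop(columns=["particle_id"])
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    return out.round(decimals)
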