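"""Brightfield particle detection by gray-level thresholding.

Particles are dark objects on a light background.  The threshold follows
the midpoint rule used for static-imaging particle analysis: T = (B + D)/2
where B is the background intensity and D the dark intensity at the
particle borders.  Contours are extracted sub-pixel at the threshold
level set (marching squares), which avoids the staircase bias a
pixel-boundary chain would put on perimeter-sensitive descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon as _ShapelyPolygon
from skimage import measure as _skmeasure

from . import geometry


@dataclass
class GrayImage:
    """A grayscale brightfield frame with physical pixel calibration."""

    pixels: np.ndarray  # 2-D float intensities
    pixel_size: float = 1.25  # um / pixel
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class ParticleRegion:
    """One connected dark region: filled mask plus sub-pixel contour."""

    id: int
    slices: tuple  # bounding-box slices into the full image
    mask_local: np.ndarray  # boolean mask within the bounding box, holes filled
    contour: np.ndarray  # (N, 2) sub-pixel (row, col) polygon, full-image coords
    mean_interior_intensity: float
    touches_border: bool

    @property
    def n_pixels(self) -> int:
        return int(self.mask_local.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = np.nonzero(self.mask_local)
        return (
            float(r.mean()) + self.slices[0].start,
            float(c.mean()) + self.slices[1].start,
        )

    def mask_full(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices] = self.mask_local
        return out


@dataclass
class ThresholdResult:
    threshold: float
    background: float
    dark_edge: float

    def __float__(self) -> float:
        return self.threshold


@dataclass
class DetectionQuality:
    """How well one detected region reproduces a ground-truth particle."""

    region_id: int
    matched_truth_id: int | None
    iou: float
    fragmented: bool
    high_resolution: bool


def compute_threshold(
    image: GrayImage,
    background: float | None = None,
    dark_edge: float | None = None,
    gradient_percentile: float = 90.0,
    dark_percentile: float = 1.0,
) -> ThresholdResult:
    """Midpoint threshold T = (B + D) / 2.

    ``background`` and ``dark_edge`` may be given explicitly; in auto mode
    B is the histogram mode and D the ``dark_percentile``-th percentile of
    intensities on strong-gradient pixels (the dark center of particle
    borders).
    """
    px = image.pixels
    if px.max() == px.min():
        raise ValueError("no contrast: image is flat")
    if background is None:
        hist, edges = np.histogram(px, bins=256)
        background = float((edges[:-1] + edges[1:])[np.argmax(hist)] / 2.0)
    if dark_edge is None:
        gr = ndimage.sobel(px, axis=0) ** 2 + ndimage.sobel(px, axis=1) ** 2
        if not np.any(gr > 0):
            raise ValueError("no contrast: no gradient ridges found")
        strong = gr >= np.percentile(gr[gr > 0], gradient_percentile)
        # sample a 2-px band around the ridges so the dark side of each
        # border (the particle interior adjacent to the edge) is included
        band = ndimage.binary_dilation(strong, structure=_STRUCT8, iterations=2)
        dark_edge = float(np.percentile(px[band], dark_percentile))
    if background == dark_edge:
        raise ValueError("no contrast: background equals dark edge")
    return ThresholdResult((background + dark_edge) / 2.0, background, dark_edge)


_STRUCT8 = np.ones((3, 3), dtype=bool)


def _region_contour(
    image: GrayImage, threshold: float, slices, mask_local: np.ndarray
) -> np.ndarray:
    """Sub-pixel contour of one region at the threshold level set."""
    r0, c0 = slices[0].start, slices[1].start
    pad = 2
    rlo, rhi = max(r0 - pad, 0), min(slices[0].stop + pad, image.pixels.shape[0])
    clo, chi = max(c0 - pad, 0), min(slices[1].stop + pad, image.pixels.shape[1])
    sub = image.pixels[rlo:rhi, clo:chi].copy()
    # suppress neighbouring particles so only this region's level set survives
    keep = np.zeros(sub.shape, dtype=bool)
    keep[r0 - rlo : r0 - rlo + mask_local.shape[0], c0 - clo : c0 - clo + mask_local.shape[1]] = (
        mask_local
    )
    keep = ndimage.binary_dilation(keep, structure=_STRUCT8, iterations=2)
    high = max(float(sub.max()), threshold + 1.0)
    sub[~keep] = high

    contours = _skmeasure.find_contours(sub, threshold)
    rr, cc = np.nonzero(mask_local)
    centroid = Point(rr.mean() + r0 - rlo, cc.mean() + c0 - clo)
    best, best_area = None, -1.0
    for cont in contours:
        if len(cont) < 4 or not np.allclose(cont[0], cont[-1]):
            continue
        try:
            poly = _ShapelyPolygon(cont)
        except Exception:
            continue
        if poly.is_valid and poly.area > best_area and poly.contains(centroid):
            best, best_area = cont, poly.area
    if best is None:
        # open level set (border-touching) or noise: fall back to the
        # mask's own 0.5-level outline
        padded = np.pad(mask_local.astype(float), 1)
        conts = _skmeasure.find_contours(padded, 0.5)
        best = max(conts, key=len) - 1.0 + np.array([r0 - rlo, c0 - clo])
    return best[:-1] + np.array([rlo, clo]) if np.allclose(best[0], best[-1]) else best + np.array(
        [rlo, clo]
    )


def segment(
    image: GrayImage,
    threshold: float | ThresholdResult,
    min_ecd: float = 1.0,
    exclude_border: bool = True,
) -> list[ParticleRegion]:
    """Detect dark particles: foreground = pixels below the threshold.

    8-connected labeling, holes filled before measurement, regions with
    raster ECD below ``min_ecd`` (um) discarded, border-touching regions
    flagged and dropped when ``exclude_border``.
    """
    t = float(threshold)
    fg = image.pixels < t
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    regions: list[ParticleRegion] = []
    rid = 0
    for lab, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None:
            continue
        mask_local = labels[slc] == lab
        npx = int(mask_local.sum())
        ecd_um = geometry.ecd_from_area(npx) * image.pixel_size
        if ecd_um < min_ecd:
            continue
        touches = (
            slc[0].start == 0
            or slc[1].start == 0
            or slc[0].stop == image.pixels.shape[0]
            or slc[1].stop == image.pixels.shape[1]
        )
        if touches and exclude_border:
            continue
        contour = _region_contour(image, t, slc, mask_local)
        if len(contour) < 3:
            continue
        interior = image.pixels[slc][mask_local]
        regions.append(
            ParticleRegion(
                id=rid,
                slices=slc,
                mask_local=mask_local,
                contour=contour,
                mean_interior_intensity=float(interior.mean()),
                touches_border=touches,
            )
        )
        rid += 1
    return regions


def _iou(region: ParticleRegion, truth, shape) -> float:
    a = region.mask_full(shape)
    b = truth.mask_full(shape)
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return float(inter / np.logical_or(a, b).sum())


def match_to_truth(
    regions,
    ground_truth,
    image_shape,
    iou_threshold: float = 0.85,
    overlap_fraction: float = 0.1,
) -> list[DetectionQuality]:
    """Greedy max-IoU matching of detections to ground-truth particles.

    A truth particle substantially overlapped by two or more detections is
    fragmented; a detection is high-resolution when its IoU reaches
    ``iou_threshold`` and its truth is not fragmented.
    """
    pairs = []
    overlaps_per_truth: dict[int, int] = {}
    iou_matrix: dict[tuple[int, int], float] = {}
    for r in regions:
        for t in ground_truth:
            iou = _iou(r, t, image_shape)
            if iou > 0:
                iou_matrix[(r.id, t.id)] = iou
                pairs.append((iou, r.id, t.id))
                inter = np.logical_and(
                    r.mask_full(image_shape), t.mask_full(image_shape)
                ).sum()
                smaller = min(r.n_pixels, t.mask_local.sum())
                if smaller > 0 and inter / smaller >= overlap_fraction:
                    overlaps_per_truth[t.id] = overlaps_per_truth.get(t.id, 0) + 1

    pairs.sort(reverse=True)
    matched_r: set[int] = set()
    matched_t: set[int] = set()
    assignment: dict[int, tuple[int, float]] = {}
    for iou, rid, tid in pairs:
        if rid in matched_r or tid in matched_t:
            continue
        assignment[rid] = (tid, iou)
        matched_r.add(rid)
        matched_t.add(tid)

    out = []
    for r in regions:
        tid, iou = assignment.get(r.id, (None, 0.0))
        frag = tid is not None and overlaps_per_truth.get(tid, 0) >= 2
        out.append(
            DetectionQuality(
                region_id=r.id,
                matched_truth_id=tid,
                iou=iou,
                fragmented=frag,
                high_resolution=(iou >= iou_threshold) and not frag,
            )
        )
    return out


def high_resolution_fraction(qualities) -> float:
    """Fraction of detections judged high-resolution."""
    if not qualities:
        return float("nan")
    return sum(q.high_resolution for q in qualities) / len(qualities)
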