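"""Phantom particle scenes and synthetic Raman spectra with known truth.

The generator emulates the four particle classes used for subvisible
particle method development:

- ``sphere``: monodisperse polystyrene-like microspheres (high optical
  contrast, opaque);
- ``lithographic``: monodisperse elongated photoresist-like shapes with a
  well-defined outline (SU-8-like);
- ``flake``: polydisperse translucent irregular flakes (ETFE-like),
  modelled as roughness-perturbed star-convex polygons;
- ``aggregate``: amorphous/fibrillar blobs grown by seeded random disk
  accretion with a tunable elongation bias (proteinaceous-like).

Every particle carries ground truth computed from its continuous
generating polygon (never from the raster), so segmentation and
morphology can be validated by parameter recovery.  Spectra are sums of
Lorentzian bands whose amplitude scales with particle diameter and
thickness relative to the 3 um laser spot, so signal-to-noise falls for
small or thin particles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from shapely.geometry import MultiPolygon, Point
from shapely.ops import unary_union
from skimage.draw import polygon as _draw_polygon

from . import geometry, raman
from .morphology import MorphologyRecord, measure_polygon
from .segmentation import GrayImage

SHAPE_CLASSES = ("sphere", "lithographic", "flake", "aggregate")

#: default 8-bit gray levels: light background, opaque and translucent particles
BACKGROUND_LEVEL = 200.0
OPAQUE_LEVEL = 60.0
TRANSLUCENT_LEVEL = 150.0

#: detector pixel calibration (um per pixel)
DEFAULT_PIXEL_SIZE = 1.25

#: Raman laser spot diameter (um); particles smaller/thinner than this lose signal
LASER_SPOT_UM = 3.0

#: noise level (fraction of the strongest band amplitude) giving peak
#: S/N ~ 100 for particles at or above the laser spot: the high-S/N regime
HIGH_SNR_NOISE_SIGMA = 0.01

#: flakes are thin relative to their in-plane extent
FLAKE_THICKNESS_RATIO = 1.0 / 8.0

_SUPERSAMPLE = 4


class SceneCompositionError(RuntimeError):
    """Raised when elements cannot be placed without overlap."""

    def __init__(self, unplaced_ids):
        self.unplaced_ids = list(unplaced_ids)
        super().__init__(f"could not place elements without overlap: {self.unplaced_ids}")


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one phantom particle."""

    shape_class: str
    ecd_target: float  # um
    aspect_target: float = 1.0
    gray_level_particle: float = OPAQUE_LEVEL
    gray_level_background: float = BACKGROUND_LEVEL
    seed: int = 0
    roughness: float = 0.35  # flakes: boundary perturbation amplitude
    elongation_bias: float = 0.0  # aggregates: 0 = isotropic, 1 = chain-like

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"shape_class must be one of {SHAPE_CLASSES}")
        if self.ecd_target <= 0:
            raise ValueError("ecd_target must be positive")
        if not (0 < self.aspect_target <= 1):
            raise ValueError("aspect_target must lie in (0, 1]")
        if self.gray_level_particle >= self.gray_level_background:
            raise ValueError("dark-on-light: particle gray level must be below background")
        if self.roughness < 0:
            raise ValueError("roughness must be non-negative")
        if not (0 <= self.elongation_bias <= 1):
            raise ValueError("elongation_bias must lie in [0, 1]")


@dataclass
class PhantomElement:
    """One generated particle: continuous polygon (um, centred) + gray level."""

    shape_class: str
    polygon: np.ndarray  # (N, 2) um, centred near the origin
    gray_level: float
    spec: ShapeSpec
    _record: MorphologyRecord | None = field(default=None, repr=False)

    @property
    def record(self) -> MorphologyRecord:
        """Ground-truth descriptors from the continuous polygon."""
        if self._record is None:
            self._record = measure_polygon(self.polygon, mean_intensity=self.gray_level)
        return self._record


@dataclass
class GroundTruthParticle:
    id: int
    shape_class: str
    polygon_um: np.ndarray  # (N, 2) global (row, col) um coordinates
    record: MorphologyRecord
    gray_level: float
    slices: tuple
    mask_local: np.ndarray

    def mask_full(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices] = self.mask_local
        return out


@dataclass
class PhantomScene:
    image: GrayImage
    ground_truth: list[GroundTruthParticle]


def _centered(poly: np.ndarray) -> np.ndarray:
    return poly - poly.mean(axis=0)


def make_sphere(spec: ShapeSpec, pixel_size: float = DEFAULT_PIXEL_SIZE) -> PhantomElement:
    """Opaque disk; ECD, aspect, circularity and convexity all exact."""
    if spec.shape_class != "sphere":
        raise ValueError("spec.shape_class must be 'sphere'")
    if spec.ecd_target < 2 * pixel_size:
        raise ValueError(
            f"ecd_target {spec.ecd_target} um below resolvable size (2 px = {2 * pixel_size} um)"
        )
    poly = geometry.regular_polygon(spec.ecd_target / 2.0, n=256)
    # rescale the n-gon so its polygonal area gives exactly the target ECD
    scale = (np.pi * (spec.ecd_target / 2.0) ** 2 / geometry.polygon_area(poly)) ** 0.5
    return PhantomElement("sphere", poly * scale, spec.gray_level_particle, spec)


def make_lithographic(spec: ShapeSpec) -> PhantomElement:
    """Deterministic elongated template with exact Feret ratio.

    An elliptical 256-gon with semi-axes a and b = a * aspect_target gives
    Fmin/Fmax = aspect_target and ECD = ecd_target by construction, and is
    identical across calls at a fixed spec (monodisperse).
    """
    if spec.shape_class != "lithographic":
        raise ValueError("spec.shape_class must be 'lithographic'")
    a = spec.ecd_target / (2.0 * np.sqrt(spec.aspect_target))
    b = a * spec.aspect_target
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    poly = np.column_stack([b * np.sin(theta), a * np.cos(theta)])
    # rescale so the polygonal (not ideal-ellipse) area hits the ECD target
    scale = (np.pi * (spec.ecd_target / 2.0) ** 2 / geometry.polygon_area(poly)) ** 0.5
    return PhantomElement("lithographic", poly * scale, spec.gray_level_particle, spec)


def make_flake(spec: ShapeSpec) -> PhantomElement:
    """Translucent star-convex polygon with random smooth roughness.

    Radii follow r(theta) = R * (1 + roughness * g(theta)) with g a
    band-limited random Fourier series; roughness -> 0 recovers a disk.
    """
    if spec.shape_class != "flake":
        raise ValueError("spec.shape_class must be 'flake'")
    rng = np.random.default_rng(spec.seed)
    n = 180
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    g = np.zeros(n)
    for m in range(2, 9):
        g += (rng.normal() * np.cos(m * theta) + rng.normal() * np.sin(m * theta)) / m
    peak = np.abs(g).max()
    if peak > 0:
        g *= 0.95 / peak  # keep radii strictly positive for roughness <= 1
    radii = 1.0 + min(spec.roughness, 1.0) * g
    poly = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    scale = (np.pi * (spec.ecd_target / 2.0) ** 2 / geometry.polygon_area(poly)) ** 0.5
    return PhantomElement("flake", _centered(poly * scale), spec.gray_level_particle, spec)


def make_aggregate(spec: ShapeSpec, n_blobs: int = 18) -> PhantomElement:
    """Blob grown by seeded random disk accretion.

    Each step attaches a disk to a randomly chosen existing disk; with
    probability ``elongation_bias`` the growth direction concentrates
    along a fixed random axis, so a higher bias yields statistically more
    elongated particles.
    """
    if spec.shape_class != "aggregate":
        raise ValueError("spec.shape_class must be 'aggregate'")
    rng = np.random.default_rng(spec.seed)
    axis = rng.uniform(0.0, 2.0 * np.pi)
    r0 = 1.0
    centers = [np.zeros(2)]
    radii = [r0]
    for _ in range(n_blobs - 1):
        parent = rng.integers(len(centers))
        if rng.random() < spec.elongation_bias:
            direction = axis + rng.choice([0.0, np.pi]) + rng.normal(0.0, 0.3)
        else:
            direction = rng.uniform(0.0, 2.0 * np.pi)
        r = r0 * rng.uniform(0.5, 1.0)
        step = radii[parent] + 0.7 * r
        centers.append(centers[parent] + step * np.array([np.cos(direction), np.sin(direction)]))
        radii.append(r)
    union = unary_union([Point(*c).buffer(r, quad_segs=16) for c, r in zip(centers, radii)])
    if isinstance(union, MultiPolygon):
        union = max(union.geoms, key=lambda p: p.area)
    poly = np.asarray(union.exterior.coords)[:-1]
    scale = (np.pi * (spec.ecd_target / 2.0) ** 2 / geometry.polygon_area(poly)) ** 0.5
    return PhantomElement("aggregate", _centered(poly * scale), spec.gray_level_particle, spec)


_MAKERS = {
    "sphere": make_sphere,
    "lithographic": make_lithographic,
    "flake": make_flake,
    "aggregate": make_aggregate,
}


def make_element(spec: ShapeSpec, **kwargs) -> PhantomElement:
    return _MAKERS[spec.shape_class](spec, **kwargs)


def _polygon_coverage(poly_px: np.ndarray, image_shape) -> tuple[tuple, np.ndarray]:
    """Area-coverage raster of a polygon given in (row, col) pixel coords.

    Coverage is estimated by 4x4 supersampling, i.e. area-weighted
    boundary pixels, so that thresholding the rendered edge at the
    mid-level reproduces the continuous geometry.
    """
    s = _SUPERSAMPLE
    rmin = max(int(np.floor(poly_px[:, 0].min())) - 1, 0)
    cmin = max(int(np.floor(poly_px[:, 1].min())) - 1, 0)
    rmax = min(int(np.ceil(poly_px[:, 0].max())) + 1, image_shape[0] - 1)
    cmax = min(int(np.ceil(poly_px[:, 1].max())) + 1, image_shape[1] - 1)
    h, w = rmax - rmin + 1, cmax - cmin + 1
    rr = (poly_px[:, 0] - rmin + 0.5) * s - 0.5
    cc = (poly_px[:, 1] - cmin + 0.5) * s - 0.5
    fill_r, fill_c = _draw_polygon(rr, cc, shape=(h * s, w * s))
    super_mask = np.zeros((h * s, w * s), dtype=np.float32)
    super_mask[fill_r, fill_c] = 1.0
    coverage = super_mask.reshape(h, s, w, s).mean(axis=(1, 3))
    return (slice(rmin, rmax + 1), slice(cmin, cmax + 1)), coverage


def compose_scene(
    elements,
    image_size: tuple[int, int] = (512, 512),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    background_level: float = BACKGROUND_LEVEL,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int = 0,
    allow_overlap: bool = False,
    max_tries: int = 500,
    bit_depth: int = 8,
) -> PhantomScene:
    """Place elements at random non-overlapping positions and render.

    Rendering: anti-aliased coverage fill per element, then optional
    Gaussian blur (optics) and additive Gaussian noise (sensor), clipped
    to the bit range.  Ground truth (continuous descriptors + raster
    mask) is retained per element.  Raises :class:`SceneCompositionError`
    when placement fails after bounded retries.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    canvas = np.full((h, w), float(background_level))
    placed: list[tuple[np.ndarray, float]] = []  # (center px, bounding radius px)
    truth: list[GroundTruthParticle] = []
    unplaced = []

    for idx, el in enumerate(list(elements)):
        rad_px = el.record.feret_max / 2.0 / pixel_size + 2.0
        if 2 * rad_px >= min(h, w):
            unplaced.append(idx)
            continue
        pos = None
        for _ in range(max_tries):
            cand = np.array(
                [rng.uniform(rad_px, h - 1 - rad_px), rng.uniform(rad_px, w - 1 - rad_px)]
            )
            if allow_overlap or all(
                np.hypot(*(cand - c)) > rad_px + r for c, r in placed
            ):
                pos = cand
                break
        if pos is None:
            unplaced.append(idx)
            continue
        placed.append((pos, rad_px))

        poly_px = el.polygon / pixel_size + pos
        slices, coverage = _polygon_coverage(poly_px, (h, w))
        patch = background_level + coverage * (el.gray_level - background_level)
        canvas[slices] = np.minimum(canvas[slices], patch)  # darker particle wins
        truth.append(
            GroundTruthParticle(
                id=len(truth),
                shape_class=el.shape_class,
                polygon_um=poly_px * pixel_size,
                record=replace(el.record, particle_id=len(truth)),
                gray_level=el.gray_level,
                slices=slices,
                mask_local=coverage >= 0.5,
            )
        )

    if unplaced:
        raise SceneCompositionError(unplaced)

    if blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, blur_sigma)
    if noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    canvas = np.clip(canvas, 0.0, 2 ** bit_depth - 1)
    return PhantomScene(GrayImage(canvas, pixel_size, bit_depth), truth)


# ---------------------------------------------------------------------------
# populations

def flake_population(
    n: int,
    median_ecd: float = 25.0,
    gsd: float = 1.6,
    roughness: float = 0.35,
    gray_level: float = TRANSLUCENT_LEVEL,
    seed: int = 0,
) -> list[PhantomElement]:
    """Polydisperse translucent flakes with lognormal ECD.

    ``gsd`` is the geometric standard deviation of the lognormal size law
    (the distributional form is an assumption; real abraded-polymer size
    laws are not tabulated).
    """
    rng = np.random.default_rng(seed)
    ecds = np.exp(rng.normal(np.log(median_ecd), np.log(gsd), n))
    return [
        make_flake(
            ShapeSpec(
                "flake",
                ecd_target=float(e),
                gray_level_particle=gray_level,
                seed=int(rng.integers(2 ** 31)),
                roughness=roughness,
            )
        )
        for e in ecds
    ]


def aggregate_population(
    n: int,
    median_ecd: float = 40.0,
    gsd: float = 1.5,
    elongation_bias: float = 0.0,
    gray_level: float = TRANSLUCENT_LEVEL,
    seed: int = 0,
) -> list[PhantomElement]:
    """Polydisperse proteinaceous-like accretion blobs."""
    rng = np.random.default_rng(seed)
    ecds = np.exp(rng.normal(np.log(median_ecd), np.log(gsd), n))
    return [
        make_aggregate(
            ShapeSpec(
                "aggregate",
                ecd_target=float(e),
                gray_level_particle=gray_level,
                seed=int(rng.integers(2 ** 31)),
                elongation_bias=elongation_bias,
            )
        )
        for e in ecds
    ]


def flake_thickness(ecd: float) -> float:
    """Thin-flake thickness model: thickness = ECD / 8, capped at the ECD."""
    return min(ecd * FLAKE_THICKNESS_RATIO, ecd)


# ---------------------------------------------------------------------------
# spectra

@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for one synthetic particle spectrum."""

    material: str | None = None  # PS | ETFE | protein (supplies bands/amps/widths)
    band_positions: tuple | None = None
    band_widths: float | tuple | None = None  # FWHM, cm^-1; material default or 8
    band_amplitudes: tuple | None = None
    particle_ecd: float = 25.0  # um
    particle_thickness: float | None = None  # um; defaults to the ECD (sphere)
    noise_sigma: float = HIGH_SNR_NOISE_SIGMA
    baseline_amplitude: float = 0.05
    grid: tuple[float, float, float] = raman.DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.material is None and self.band_positions is None:
            raise ValueError("either material or band_positions must be given")
        if self.band_positions is not None and len(self.band_positions) == 0:
            raise ValueError("band list must not be empty")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.particle_ecd <= 0:
            raise ValueError("particle_ecd must be positive")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        t = self.thickness
        if t <= 0 or t > self.particle_ecd * (1 + 1e-9):
            raise ValueError("thickness must lie in (0, ecd]")

    @property
    def thickness(self) -> float:
        return self.particle_ecd if self.particle_thickness is None else self.particle_thickness


def size_amplitude_factor(ecd: float, thickness: float, spot: float = LASER_SPOT_UM) -> float:
    """Signal attenuation for particles smaller/thinner than the laser spot.

    Linear in each of diameter and thickness, capped at 1 once both reach
    the spot diameter; monotone non-decreasing in both arguments.
    """
    return (min(ecd, spot) / spot) * (min(thickness, spot) / spot)


def synth_spectrum(spec: SpectrumSpec) -> raman.Spectrum:
    """Lorentzian band sum x size factor + smooth baseline drift + noise."""
    lo, hi, step = spec.grid
    w = np.arange(lo, hi + step / 2, step)
    if spec.band_positions is not None:
        positions = np.asarray(spec.band_positions, dtype=float)
        amps = (
            np.ones_like(positions)
            if spec.band_amplitudes is None
            else np.asarray(spec.band_amplitudes, dtype=float)
        )
        widths = 8.0 if spec.band_widths is None else spec.band_widths
    else:
        positions = np.asarray(raman.MATERIAL_BANDS[spec.material], dtype=float)
        amps = np.asarray(
            spec.band_amplitudes
            if spec.band_amplitudes is not None
            else raman.MATERIAL_AMPS[spec.material],
            dtype=float,
        )
        widths = (
            raman.MATERIAL_WIDTHS[spec.material] if spec.band_widths is None else spec.band_widths
        )
    if np.any((positions < lo) | (positions > hi)):
        raise ValueError("band positions must lie inside the grid")

    f = size_amplitude_factor(spec.particle_ecd, spec.thickness)
    signal = f * raman.lorentzian_sum(w, positions, widths, amps)

    rng = np.random.default_rng(spec.seed)
    x = (w - lo) / (hi - lo)
    baseline = spec.baseline_amplitude * (
        rng.uniform(0, 1) + rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * x ** 2
    )
    noise = rng.normal(0.0, spec.noise_sigma, w.shape) if spec.noise_sigma > 0 else 0.0
    meta = {
        "material": spec.material,
        "particle_ecd": spec.particle_ecd,
        "particle_thickness": spec.thickness,
        "noise_sigma": spec.noise_sigma,
        "size_factor": f,
        "seed": spec.seed,
    }
    return raman.Spectrum(w, signal + baseline + noise, meta)


# ---------------------------------------------------------------------------
# scene I/O: TIFF image + plain-text ground-truth sidecar

def write_scene(scene: PhantomScene, image_path, truth_path) -> None:
    img = scene.image
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(image_path), np.round(img.pixels).astype(dtype))
    particles = []
    for t in scene.ground_truth:
        r = t.record
        particles.append(
            {
                "id": t.id,
                "shape_class": t.shape_class,
                "ecd": r.ecd,
                "feret_min": r.feret_min,
                "feret_max": r.feret_max,
                "area": r.area,
                "perimeter": r.perimeter,
                "centroid_um": list(t.polygon_um.mean(axis=0)),
                "gray_level": t.gray_level,
                "polygon_um": np.round(t.polygon_um, 4).tolist(),
            }
        )
    Path(truth_path).write_text(
        json.dumps({"pixel_size": img.pixel_size, "particles": particles})
    )


def read_image(path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> GrayImage:
    arr = tifffile.imread(str(path))
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr.astype(float), pixel_size, bit_depth)
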