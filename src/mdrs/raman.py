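"""Raman spectra: containers, preprocessing, library scoring, identity.

The chemical correlation score between a particle spectrum and a
reference is the Pearson correlation of the two baseline-corrected
intensity vectors on a shared wavenumber window, clipped to [0, 1].
Scores of 1 mean spectra identical up to a positive affine intensity
transform; 0 means no (or negative) linear association.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Characteristic band positions (cm^-1) and relative peak amplitudes of the
# three particle chemistries handled by the built-in library.
PS_BANDS = (621.0, 795.0, 1000.0, 1031.0, 1155.0, 1450.0, 1583.0, 1602.0)
PS_AMPS = (0.45, 0.25, 1.00, 0.55, 0.30, 0.35, 0.30, 0.60)

ETFE_BANDS = (835.0, 1444.0)
ETFE_AMPS = (1.00, 0.75)

# disulfide (500-550), tryptophan 770, phenylalanine 1003, amide III 1230,
# CH deformation 1340, asymmetric CH2 1400, CH2/CH3 deformation 1448 and
# amide I 1670-1690 (the dominant protein band in the fingerprint window);
# ranges represented by centres.  Protein bands are broad relative to the
# sharp polymer bands, so each carries its own width.
PROTEIN_BANDS = (525.0, 770.0, 1003.0, 1230.0, 1340.0, 1400.0, 1448.0, 1680.0)
PROTEIN_AMPS = (0.30, 0.20, 0.55, 0.60, 0.40, 0.45, 0.60, 1.00)
PROTEIN_WIDTHS = (25.0, 15.0, 10.0, 30.0, 25.0, 25.0, 20.0, 35.0)

MATERIAL_BANDS = {"PS": PS_BANDS, "ETFE": ETFE_BANDS, "protein": PROTEIN_BANDS}
MATERIAL_AMPS = {"PS": PS_AMPS, "ETFE": ETFE_AMPS, "protein": PROTEIN_AMPS}
MATERIAL_WIDTHS = {"PS": 8.0, "ETFE": 8.0, "protein": PROTEIN_WIDTHS}

#: default scoring windows (cm^-1): the fingerprint region for the polymers,
#: 900-1800 for protein (the ~770 tryptophan band is too weak to score on)
DEFAULT_WINDOWS = {"PS": (700.0, 1800.0), "ETFE": (700.0, 1800.0), "protein": (900.0, 1800.0)}

DEFAULT_GRID = (200.0, 1800.0, 1.0)

#: sentinel cap for a noise-free S/N estimate
SNR_CAP = 1e6

MIN_WINDOW_POINTS = 16


@dataclass
class Spectrum:
    """A single Raman spectrum on a strictly ascending wavenumber grid."""

    wavenumbers: np.ndarray  # cm^-1
    intensities: np.ndarray  # arbitrary units
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if len(self.wavenumbers) < 2 or np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


def lorentzian_sum(grid, positions, widths, amplitudes) -> np.ndarray:
    """Sum of Lorentzian bands; ``widths`` are FWHM in cm^-1."""
    grid = np.asarray(grid, dtype=float)
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("at least one band position required")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), positions.shape)
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), positions.shape)
    out = np.zeros_like(grid)
    for p, w, a in zip(positions, widths, amplitudes):
        gamma = w / 2.0  # HWHM
        out += a * gamma ** 2 / ((grid - p) ** 2 + gamma ** 2)
    return out


def make_reference(
    material: str,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    band_width: float | tuple | None = None,
) -> Spectrum:
    """Noise-free analytic reference spectrum for a built-in material."""
    if material not in MATERIAL_BANDS:
        raise KeyError(f"unknown material {material!r}; have {sorted(MATERIAL_BANDS)}")
    lo, hi, step = grid
    w = np.arange(lo, hi + step / 2, step)
    widths = MATERIAL_WIDTHS[material] if band_width is None else band_width
    y = lorentzian_sum(w, MATERIAL_BANDS[material], widths, MATERIAL_AMPS[material])
    return Spectrum(w, y, meta={"material": material, "reference": True})


@dataclass
class LibraryEntry:
    name: str
    spectrum: Spectrum
    window: tuple[float, float]


@dataclass
class ReferenceLibrary:
    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("library entry names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def default_library(grid: tuple[float, float, float] = DEFAULT_GRID) -> ReferenceLibrary:
    """Built-in PS / ETFE / protein references with their scoring windows."""
    return ReferenceLibrary(
        [
            LibraryEntry(m, make_reference(m, grid), DEFAULT_WINDOWS[m])
            for m in ("PS", "ETFE", "protein")
        ]
    )


@dataclass
class CorrelationResult:
    particle_id: int | None
    scores: dict  # name -> score in [0, 1] (None when scoring failed)
    best_match: str
    best_score: float


def _crop(spectrum: Spectrum, window: tuple[float, float]) -> Spectrum:
    lo, hi = window
    m = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if m.sum() < MIN_WINDOW_POINTS:
        raise ValueError(
            f"window {window} covers {int(m.sum())} points of the grid; need >= {MIN_WINDOW_POINTS}"
        )
    return Spectrum(spectrum.wavenumbers[m], spectrum.intensities[m], dict(spectrum.meta))


def _linear_baseline(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Line through low-percentile anchors of the two end segments."""
    seg = max(len(y) // 10, 3)
    x0, x1 = w[:seg].mean(), w[-seg:].mean()
    y0 = np.percentile(y[:seg], 5)
    y1 = np.percentile(y[-seg:], 5)
    if x1 == x0:
        return np.full_like(y, y0)
    return y0 + (y1 - y0) * (w - x0) / (x1 - x0)


def _rolling_min_baseline(y: np.ndarray, size: int = 75) -> np.ndarray:
    from scipy.ndimage import minimum_filter1d, uniform_filter1d

    return uniform_filter1d(minimum_filter1d(y, size=size), size=size)


def preprocess(
    spectrum: Spectrum,
    window: tuple[float, float] | None = None,
    baseline: str = "linear",
    normalize: bool = True,
) -> Spectrum:
    """Crop to window, subtract baseline, optionally min-max normalize."""
    s = _crop(spectrum, window) if window is not None else spectrum
    w, y = s.wavenumbers, s.intensities.copy()
    if baseline == "linear":
        y = y - _linear_baseline(w, y)
    elif baseline == "rolling_min":
        y = y - _rolling_min_baseline(y)
    elif baseline != "none":
        raise ValueError(f"unknown baseline method {baseline!r}")
    if normalize:
        lo, hi = y.min(), y.max()
        if hi > lo:
            y = (y - lo) / (hi - lo)
        else:
            y = np.zeros_like(y)
    return Spectrum(w, y, dict(s.meta))


def correlation_score(
    sample: Spectrum,
    reference: Spectrum,
    window: tuple[float, float],
    baseline: str = "linear",
) -> float:
    """Clipped Pearson correlation on the preprocessed window, in [0, 1]."""
    ref = preprocess(reference, window, baseline=baseline, normalize=True)
    # resample the sample onto the reference grid before preprocessing
    resampled = Spectrum(
        ref.wavenumbers,
        np.interp(ref.wavenumbers, sample.wavenumbers, sample.intensities),
        dict(sample.meta),
    )
    smp = preprocess(resampled, None, baseline=baseline, normalize=True)
    if np.ptp(smp.intensities) == 0 or np.ptp(ref.intensities) == 0:
        raise ValueError("uninformative spectrum: zero variance in scoring window")
    r = float(np.corrcoef(smp.intensities, ref.intensities)[0, 1])
    return max(r, 0.0)


def identify(sample: Spectrum, library: ReferenceLibrary, baseline: str = "linear") -> CorrelationResult:
    """Score against every library entry on its window; best match wins.

    Per-entry failures propagate as missing scores; ties break by library
    order.
    """
    if len(library) == 0:
        raise ValueError("empty reference library")
    scores: dict = {}
    for entry in library:
        try:
            scores[entry.name] = correlation_score(
                sample, entry.spectrum, entry.window, baseline=baseline
            )
        except ValueError:
            scores[entry.name] = None
    valid = {k: v for k, v in scores.items() if v is not None}
    if not valid:
        raise ValueError("no library entry could be scored")
    best = max(valid, key=lambda k: valid[k])  # dict order breaks ties
    return CorrelationResult(
        particle_id=sample.meta.get("particle_id"),
        scores=scores,
        best_match=best,
        best_score=valid[best],
    )


PROTEIN_MARKER_WINDOWS = ((992.0, 1008.0), (1222.0, 1238.0), (1392.0, 1408.0), (1670.0, 1690.0))


def select_protein_reference(
    candidates,
    marker_windows=PROTEIN_MARKER_WINDOWS,
) -> Spectrum:
    """Pick the candidate with the greatest summed marker-band intensity.

    Markers: phenylalanine (~1000), amide III (~1230), asymmetric CH2
    (~1400) and amide I (1670-1690 cm^-1).  Intensities are integrated
    after linear baseline correction; ties break by candidate order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate spectrum required")
    best, best_total = None, -np.inf
    for cand in candidates:
        corrected = preprocess(cand, None, baseline="linear", normalize=False)
        total = 0.0
        for lo, hi in marker_windows:
            m = (corrected.wavenumbers >= lo) & (corrected.wavenumbers <= hi)
            if not np.any(m):
                raise ValueError(f"candidate misses marker window ({lo}, {hi})")
            total += float(np.trapezoid(corrected.intensities[m], corrected.wavenumbers[m]))
        if total > best_total:
            best, best_total = cand, total
    return best


def snr_estimate(
    spectrum: Spectrum,
    band_positions,
    peak_halfwidth: float = 10.0,
    exclusion_halfwidth: float = 25.0,
) -> float:
    """Peak signal-to-noise: mean band height over robust noise SD.

    Noise is 1.4826 * MAD of the baseline-corrected intensities on the
    longest band-free stretch of the grid.  A noise-free spectrum returns
    the ``SNR_CAP`` sentinel.
    """
    positions = np.atleast_1d(np.asarray(band_positions, dtype=float))
    w = spectrum.wavenumbers
    lo, hi = spectrum.span
    if np.any((positions < lo) | (positions > hi)):
        raise ValueError("band positions must lie inside the spectrum span")
    corrected = preprocess(spectrum, None, baseline="linear", normalize=False)
    y = corrected.intensities

    free = np.ones(len(w), dtype=bool)
    for p in positions:
        free &= np.abs(w - p) > exclusion_halfwidth
    # longest contiguous signal-free run
    best_len, best_start, run, start = 0, -1, 0, 0
    for i, f in enumerate(free):
        if f:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
    if best_len < MIN_WINDOW_POINTS:
        raise ValueError("no signal-free window available for noise estimation")
    noise_seg = y[best_start : best_start + best_len]
    # high-frequency noise via the second difference (variance 6 sigma^2 for
    # white noise), so smooth band tails and baseline residue do not count
    d2 = np.diff(noise_seg, n=2)
    noise = 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / np.sqrt(6.0)

    heights = []
    for p in positions:
        m = np.abs(w - p) <= peak_halfwidth
        if np.any(m):
            heights.append(float(y[m].max()))
    if not heights:
        raise ValueError("no band lies on the grid")
    signal = float(np.mean(heights))
    if noise == 0:
        return SNR_CAP
    return min(signal / noise, SNR_CAP)


# ---------------------------------------------------------------------------
# plain-text I/O: two-column delimited spectra and a JSON library manifest

def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    header = "# wavenumber_cm-1\tintensity"
    meta = {k: v for k, v in spectrum.meta.items() if isinstance(v, (str, int, float, bool))}
    if meta:
        header = f"# meta: {json.dumps(meta, sort_keys=True)}\n" + header
    body = "\n".join(
        f"{w:.6g}\t{i:.8g}" for w, i in zip(spectrum.wavenumbers, spectrum.intensities)
    )
    path.write_text(header + "\n" + body + "\n")


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:") :])
            continue
        parts = line.replace(",", "\t").split()
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.asarray(rows)
    return Spectrum(arr[:, 0], arr[:, 1], meta)


def write_library_manifest(library: ReferenceLibrary, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for e in library:
        fname = f"{e.name}.txt"
        write_spectrum(e.spectrum, directory / fname)
        entries.append({"name": e.name, "file": fname, "window": list(e.window)})
    manifest = directory / "library.json"
    manifest.write_text(json.dumps({"entries": entries}, indent=2))
    return manifest


def read_library_manifest(manifest_path) -> ReferenceLibrary:
    manifest_path = Path(manifest_path)
    data = json.loads(manifest_path.read_text())
    entries = [
        LibraryEntry(
            d["name"],
            read_spectrum(manifest_path.parent / d["file"]),
            tuple(d["window"]),
        )
        for d in data["entries"]
    ]
    return ReferenceLibrary(entries)
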