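"""End-to-end runs: scene -> segmentation -> morphology -> distribution,
spectra -> identification, joined into one per-particle report.

A run is fully specified by a :class:`RunConfig` (YAML-loadable) and is
deterministic given its seed; the manifest written next to the outputs
reproduces the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphology, raman, segmentation, size_distribution, synthetic

log = logging.getLogger("mdrs.pipeline")

_THICKNESS_MODEL = {
    "sphere": lambda ecd: ecd,
    "lithographic": lambda ecd: ecd / 4.0,
    "flake": synthetic.flake_thickness,
    "aggregate": synthetic.flake_thickness,
}

_CLASS_MATERIAL = {
    "sphere": "PS",
    "lithographic": None,  # epoxy photoresist: not in the built-in library
    "flake": "ETFE",
    "aggregate": "protein",
}


@dataclass
class RunConfig:
    """One reproducible analysis run (synthetic or file-based inputs)."""

    out_dir: str = "mdrs_run"
    seed: int = 0
    pixel_size: float = synthetic.DEFAULT_PIXEL_SIZE  # um / px
    min_ecd: float = 5.0  # um
    size_bins: tuple = (10.0, 25.0, float("inf"))
    exclude_border: bool = True

    # --- synthetic scene (used when image_paths is empty)
    particle_class: str = "flake"
    n_particles: int = 80
    median_ecd: float = 25.0  # um
    gsd: float = 1.6
    roughness: float = 0.35
    elongation_bias: float = 0.0
    image_size: tuple = (1024, 1024)
    image_noise_sigma: float = 2.0
    image_blur_sigma: float = 0.5
    spectrum_noise_sigma: float = synthetic.HIGH_SNR_NOISE_SIGMA

    # --- file-based inputs (exclusive with synthesis)
    image_paths: tuple = ()
    spectra_dir: str | None = None
    library_manifest: str | None = None

    @property
    def synthesize(self) -> bool:
        return len(self.image_paths) == 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("size_bins", "image_size", "image_paths"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@dataclass
class RunResult:
    report: pd.DataFrame
    distribution: size_distribution.SizeDistribution
    summary: dict
    manifest: dict


def _bin_label(ecd: float, edges) -> str:
    idx = np.searchsorted(edges, ecd, side="right") - 1
    if idx < 0 or idx >= len(edges) - 1 or ecd >= edges[-1]:
        return "out-of-range"
    return f"[{edges[idx]:g}, {edges[idx + 1]:g})"


@_stage("scene")
def _make_scenes(config: RunConfig):
    if not config.synthesize:
        return [
            synthetic.PhantomScene(synthetic.read_image(p, config.pixel_size), [])
            for p in config.image_paths
        ]
    cls = config.particle_class
    if cls == "flake":
        elements = synthetic.flake_population(
            config.n_particles,
            config.median_ecd,
            config.gsd,
            roughness=config.roughness,
            seed=config.seed,
        )
    elif cls == "aggregate":
        elements = synthetic.aggregate_population(
            config.n_particles,
            config.median_ecd,
            config.gsd,
            elongation_bias=config.elongation_bias,
            seed=config.seed,
        )
    elif cls in ("sphere", "lithographic"):
        spec = synthetic.ShapeSpec(
            cls,
            ecd_target=config.median_ecd,
            aspect_target=0.34 if cls == "lithographic" else 1.0,
        )
        elements = [synthetic.make_element(spec) for _ in range(config.n_particles)]
    else:
        raise ValueError(f"unknown particle_class {cls!r}")
    scene = synthetic.compose_scene(
        elements,
        image_size=tuple(config.image_size),
        pixel_size=config.pixel_size,
        noise_sigma=config.image_noise_sigma,
        blur_sigma=config.image_blur_sigma,
        seed=config.seed + 1,
    )
    return [scene]


@_stage("segmentation")
def _segment_scene(scene, config: RunConfig):
    thr = segmentation.compute_threshold(scene.image)
    regions = segmentation.segment(
        scene.image, thr, min_ecd=config.min_ecd, exclude_border=config.exclude_border
    )
    return thr, regions


@_stage("chemistry")
def _chemistry(scene, regions, matches, config: RunConfig, library):
    """Per-region identification; synthetic spectra come from matched truth."""
    results: dict[int, raman.CorrelationResult | None] = {}
    truth_by_id = {t.id: t for t in scene.ground_truth}
    match_by_region = {m.region_id: m.matched_truth_id for m in matches} if matches else {}
    for region in regions:
        spectrum = None
        if config.synthesize:
            tid = match_by_region.get(region.id)
            truth = truth_by_id.get(tid) if tid is not None else None
            if truth is not None:
                material = _CLASS_MATERIAL[truth.shape_class]
                if material is not None:
                    ecd = truth.record.ecd
                    spectrum = synthetic.synth_spectrum(
                        synthetic.SpectrumSpec(
                            material=material,
                            particle_ecd=ecd,
                            particle_thickness=_THICKNESS_MODEL[truth.shape_class](ecd),
                            noise_sigma=config.spectrum_noise_sigma,
                            seed=(config.seed * 100003 + truth.id) % (2 ** 31),
                        )
                    )
        elif config.spectra_dir is not None:
            path = Path(config.spectra_dir) / f"{region.id}.txt"
            if path.exists():
                spectrum = raman.read_spectrum(path)
        if spectrum is None:
            results[region.id] = None
            continue
        try:
            results[region.id] = raman.identify(spectrum, library)
        except ValueError:
            results[region.id] = None
    return results


def run(config: RunConfig) -> RunResult:
    """Execute a full run and write report, distribution, summary, manifest.

    Deterministic given the seed; any stage error aborts with a
    stage-tagged message and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_inner(config, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_inner(config: RunConfig, out_dir: Path, written: list[Path]) -> RunResult:
    library = (
        raman.read_library_manifest(config.library_manifest)
        if config.library_manifest
        else raman.default_library()
    )
    scenes = _make_scenes(config)

    rows = []
    records = []
    n_segmented = 0
    ref_names = [e.name for e in library]
    edges = np.asarray(config.size_bins, dtype=float)
    for scene_idx, scene in enumerate(scenes):
        thr, regions = _segment_scene(scene, config)
        n_segmented += len(regions)
        log.info(
            "scene %d: threshold %.2f (B=%.1f, D=%.1f), %d regions",
            scene_idx,
            thr.threshold,
            thr.background,
            thr.dark_edge,
            len(regions),
        )
        matches = (
            segmentation.match_to_truth(regions, scene.ground_truth, scene.image.pixels.shape)
            if scene.ground_truth
            else []
        )
        chem = _chemistry(scene, regions, matches, config, library)
        for region in regions:
            rec = morphology.measure_region(region, scene.image)
            records.append(rec)
            row = {"scene": scene_idx, **asdict(rec)}
            res = chem.get(region.id)
            row["best_match"] = res.best_match if res else None
            row["best_score"] = res.best_score if res else np.nan
            for name in ref_names:
                row[f"score_{name}"] = (
                    res.scores.get(name) if res and res.scores.get(name) is not None else np.nan
                )
            row["size_bin"] = _bin_label(rec.ecd, edges)
            rows.append(row)

    report = pd.DataFrame(rows)
    # accounting identity: every segmented, non-excluded particle appears once
    assert len(report) == n_segmented, "report rows must equal retained regions"

    dist = size_distribution.bin_particles(records, edges)
    summary = {
        "n_particles": len(records),
        "n_excluded_from_bins": dist.n_excluded,
        "descriptors": {},
        "per_bin": {},
    }
    if records:
        df = morphology.records_to_frame(records)
        for col in df.columns.drop("particle_id"):
            summary["descriptors"][col] = {
                "mean": round(float(df[col].mean()), 2),
                "sd": round(float(df[col].std(ddof=1)), 2) if len(df) > 1 else None,
            }
        for desc in ("aspect_ratio", "circularity", "convexity", "elongation"):
            trend = size_distribution.binned_morphology_trend(records, edges, desc)
            summary["per_bin"][desc] = json.loads(trend.round(4).to_json(orient="records"))

    report_path = out_dir / "report.csv"
    report.to_csv(report_path, index=False, float_format="%.6g")
    written.append(report_path)
    dist_csv = out_dir / "distribution.csv"
    dist.to_frame().to_csv(dist_csv, index=False, float_format="%.6g")
    written.append(dist_csv)
    dist_json = out_dir / "distribution.json"
    dist_json.write_text(
        json.dumps(
            {
                "bin_edges": list(dist.bin_edges),
                "counts": dist.counts.tolist(),
                "percents": dist.percents.tolist() if dist.defined else None,
                "n_total": dist.n_total,
                "n_excluded": dist.n_excluded,
            }
        )
    )
    written.append(dist_json)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    written.append(summary_path)

    cfg = asdict(config)
    cfg["size_bins"] = [e if np.isfinite(e) else None for e in cfg["size_bins"]]
    manifest = {"config": cfg, "seed": config.seed, "package": "mdrs", "version": "0.1.0"}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)

    return RunResult(report, dist, summary, manifest)


def compare_runs(report_a: pd.DataFrame, report_b: pd.DataFrame, descriptors) -> pd.DataFrame:
    """Side-by-side mean +/- SD per descriptor with Welch t-test p-values."""
    descriptors = list(descriptors)
    if len(report_a) == 0 or len(report_b) == 0:
        raise ValueError("cannot compare an empty report")
    missing = [d for d in descriptors if d not in report_a.columns or d not in report_b.columns]
    if missing:
        raise ValueError(f"descriptors missing from a report: {missing}")
    rows = []
    for d in descriptors:
        xa, xb = report_a[d].to_numpy(float), report_b[d].to_numpy(float)
        _, p = size_distribution.welch_ttest(xa, xb)
        rows.append(
            {
                "descriptor": d,
                "mean_a": xa.mean(),
                "sd_a": xa.std(ddof=1),
                "mean_b": xb.mean(),
                "sd_b": xb.std(ddof=1),
                "abs_diff": abs(xa.mean() - xb.mean()),
                "welch_p": p,
            }
        )
    return pd.DataFrame(rows)
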