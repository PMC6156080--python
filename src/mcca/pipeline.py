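"""Orchestration of simulate -> detect -> network from a single config.

A run is driven by a plain key-value document (YAML on disk).  A master
seed is fanned out into per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is independently
reproducible; identical config + seed gives byte-identical outputs.  The
run manifest records the config, its hash, all seeds, package versions
and the per-stage output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from . import network as net
from .detection import DetectionParams, analyze_recording
from .synthetic import GeneratorConfig, KernelParams, generate_population

log = logging.getLogger("mcca.pipeline")

SMOOTH_ITER_BAND = (20, 40)


class ConfigValidationError(ValueError):
    """Raised when the run configuration fails validation."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and cause."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path = Path("mcca_out")
    seed: int = 0
    simulate: bool = True
    detect: bool = True
    network: bool = True
    traces_path: Path | None = None
    rois_path: Path | None = None
    sampling_rate_hz: float = 15.2
    roi_units: str = "um"
    bin_width_s: float = net.DEFAULT_BIN_WIDTH_S
    n_surrogates: int = 100
    n_permutations: int = 1000
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    write_movie: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["traces_path"] = None if self.traces_path is None else str(self.traces_path)
        d["rois_path"] = None if self.rois_path is None else str(self.rois_path)
        return d


_TOP_KEYS = {
    "out_dir", "seed", "simulate", "detect", "network", "traces_path",
    "rois_path", "sampling_rate_hz", "roi_units", "bin_width_s",
    "n_surrogates", "n_permutations", "log_level", "generator", "detection",
    "write_movie", "allow_nonstandard_smoothing",
}


def validate_config(raw: dict | None) -> RunConfig:
    """Build a RunConfig from a raw key-value document.

    Unknown keys are rejected (no silent typos); out-of-range values are
    reported with their key path.  ``detection.smooth_iterations`` outside
    the customary 20-40 band is rejected unless the top-level flag
    ``allow_nonstandard_smoothing`` is set.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigValidationError(f"unknown config key(s): {sorted(unknown)}")
    allow_smooth = bool(raw.pop("allow_nonstandard_smoothing", False))

    gen_raw = dict(raw.pop("generator", {}) or {})
    det_raw = dict(raw.pop("detection", {}) or {})
    try:
        for sub in ("kernel", "astrocyte_kernel"):
            if sub in gen_raw:
                gen_raw[sub] = KernelParams(**gen_raw[sub])
        if "class_rates_per_min" in gen_raw:
            gen_raw["class_rates_per_min"] = tuple(gen_raw["class_rates_per_min"])
        if "class_weights" in gen_raw:
            gen_raw["class_weights"] = tuple(gen_raw["class_weights"])
        generator = GeneratorConfig(**gen_raw)
    except TypeError as exc:
        raise ConfigValidationError(f"generator: {exc}") from exc
    except ValueError as exc:
        raise ConfigValidationError(f"generator: {exc}") from exc
    try:
        detection = DetectionParams(**det_raw)
    except TypeError as exc:
        raise ConfigValidationError(f"detection: {exc}") from exc
    except ValueError as exc:
        raise ConfigValidationError(f"detection: {exc}") from exc

    lo, hi = SMOOTH_ITER_BAND
    if not allow_smooth and not lo <= detection.smooth_iterations <= hi:
        raise ConfigValidationError(
            f"detection.smooth_iterations={detection.smooth_iterations} outside the "
            f"customary {lo}-{hi} band; set allow_nonstandard_smoothing to override"
        )

    cfg = RunConfig(generator=generator, detection=detection)
    for k, v in raw.items():
        setattr(cfg, k, v)
    cfg.out_dir = Path(cfg.out_dir)
    if cfg.traces_path is not None:
        cfg.traces_path = Path(cfg.traces_path)
    if cfg.rois_path is not None:
        cfg.rois_path = Path(cfg.rois_path)
    if cfg.bin_width_s <= 0:
        raise ConfigValidationError("bin_width_s must be positive")
    if cfg.n_permutations < 100:
        raise ConfigValidationError("n_permutations must be >= 100")
    if not cfg.simulate:
        if cfg.detect and (cfg.traces_path is None or not cfg.traces_path.exists()):
            raise ConfigValidationError(
                "detect stage enabled without simulate: traces_path must exist"
            )
    return cfg


def _child_seeds(seed: int, n: int = 3) -> list[int]:
    """Stable per-stage seeds fanned out from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2)


def _write_json(obj, path: Path) -> Path:
    path.write_text(_canonical_json(obj) + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    On stage failure a ``<stage>.partial`` marker is left next to any
    partial outputs and a StageError naming the stage is raised.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(cfg.log_level)
    root = logging.getLogger("mcca")
    root.addHandler(fh)
    try:
        return _run_stages(cfg, out)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run_stages(cfg: RunConfig, out: Path) -> dict:
    seed_sim, seed_det, seed_net = _child_seeds(cfg.seed)
    cfg_dict = cfg.to_dict()
    manifest: dict = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(_canonical_json(cfg_dict).encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": {"simulate": seed_sim, "detect": seed_det, "network": seed_net},
        "versions": {
            "mcca": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {},
    }

    stage = "simulate"
    try:
        if cfg.simulate:
            gen = dataclasses.replace(cfg.generator, seed=seed_sim)
            rec, truth = generate_population(gen)
            mio.write_traces(rec, out / "traces.csv")
            mio.write_roi_coordinates(rec.roi_xy_um, out / "rois.csv")
            truth.write(out / "truth.csv")
            manifest["outputs"][stage] = {
                "traces": str(out / "traces.csv"),
                "rois": str(out / "rois.csv"),
                "truth": str(out / "truth.csv"),
            }
            if cfg.write_movie:
                from .synthetic import make_grid_masks, render_movie

                masks = make_grid_masks(rec.n_cells, field_um=gen.field_um)
                movie = render_movie(rec, masks)
                mio.write_stack(movie.astype(np.float32), out / "movie.tif")
                mio.write_masks(masks, out / "masks.tif")
                manifest["outputs"][stage]["movie"] = str(out / "movie.tif")
                manifest["outputs"][stage]["masks"] = str(out / "masks.tif")
            traces_path = out / "traces.csv"
            rois_path = out / "rois.csv"
            fs = gen.sampling_rate_hz
        else:
            traces_path = cfg.traces_path
            rois_path = cfg.rois_path
            fs = cfg.sampling_rate_hz

        stage = "detect"
        if cfg.detect:
            rec = mio.read_traces(traces_path, fs)
            if rois_path is not None:
                rec = rec.with_coordinates(
                    mio.read_roi_coordinates(rois_path, units=cfg.roi_units)
                )
            cells = analyze_recording(rec, cfg.detection)
            events = {c.cell_id: c.events for c in cells}
            mio.write_events(events, out / "events.csv")
            mio.write_cells(cells, out / "cells.csv")
            manifest["outputs"][stage] = {
                "events": str(out / "events.csv"),
                "cells": str(out / "cells.csv"),
            }

        stage = "network"
        if cfg.network:
            if not cfg.detect:
                raise StageError("network stage requires the detect stage outputs")
            rng = np.random.default_rng(seed_net)
            neurons = [c for c in cells if c.kind == "neuron"]
            trains = [np.array([e.peak_time_s for e in c.events]) for c in neurons]
            classes = [c.activity_class for c in neurons]
            neuron_idx = [i for i, c in enumerate(cells) if c.kind == "neuron"]
            xy = rec.roi_xy_um[neuron_idx] if rec.roi_xy_um is not None else None
            duration = rec.duration_s
            raster = net.bin_raster(
                trains, duration, cfg.bin_width_s,
                cell_ids=[c.cell_id for c in neurons],
            )
            cells_df = mio.cells_to_frame(cells)
            pairs = None
            summary_extras: dict = {}
            if xy is not None and sum(t.size > 0 for t in trains) >= 2:
                pairs = net.pair_table(raster, classes, xy)
                pairs.to_csv(out / "pairs.csv", index=False)
                manifest["outputs"][stage] = {"pairs": str(out / "pairs.csv")}
                tests_report: dict = {}
                if len(pairs) >= 3 and pairs["distance_um"].nunique() > 1:
                    fit = net.distance_correlation_fit(pairs)
                    tests_report["distance_fit"] = dataclasses.asdict(fit)
                summary_extras["subgroup_pairs"] = net.subgroup_pair_summary(
                    pairs
                ).to_dict(orient="records")
                # surrogate control: mean r under the two-step shuffle
                sur_means = []
                for _ in range(cfg.n_surrogates):
                    sraster = net.shuffle_raster(
                        trains, duration, mode="full", rng=rng,
                        bin_width_s=cfg.bin_width_s,
                    )
                    try:
                        r, kept = net.pearson_matrix(sraster)
                    except net.NetworkError:
                        continue
                    iu = np.triu_indices(kept.size, k=1)
                    sur_means.append(float(np.mean(r[iu])))
                if sur_means:
                    tests_report["surrogate_mean_r"] = float(np.mean(sur_means))
                    tests_report["n_surrogates"] = len(sur_means)
                clust = net.spatial_clustering_test(
                    classes, xy, n_permutations=cfg.n_permutations, rng=rng
                )
                tests_report["spatial_clustering"] = clust.to_dict(orient="records")
                _write_json(tests_report, out / "tests.json")
                manifest["outputs"][stage]["tests"] = str(out / "tests.json")
            summary = net.population_summary(
                cells_df, field_um=rec.field_um, pairs=pairs
            )
            summary.update(summary_extras)
            _write_json(summary, out / "summary.json")
            manifest["outputs"].setdefault(stage, {})["summary"] = str(
                out / "summary.json"
            )
    except Exception as exc:
        (out / f"{stage}.partial").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    return manifest
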