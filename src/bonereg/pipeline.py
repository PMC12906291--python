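"""End-to-end workflow: simulate -> register -> elastic -> metrics ->
proximity, with every intermediate persisted and all randomness behind one
seed.

Stage outputs are pure functions of (inputs, config, seed): re-running a
config reproduces all numeric artifacts bit-identically, which is the main
point of automating a formerly manual GUI workflow.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imagecore import (max_projection, read_volume, read_zstack,
                        write_section, write_volume, write_zstack)
from .phantom import PhantomSpec, make_phantom
from .template import segment_cortices
from .slicefinder import extract_oblique_slice, find_cutting_plane
from .elastic import BSplineGrid, elastic_register
from .evalmetrics import metrics_report, split_regions
from .proximity import (best_focus_index, compare_groups, gap_restrict,
                        min_distances, positive_mask, significance_stars)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, partial outputs persist."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config for the whole workflow; YAML round-trippable.

    Either ``simulate=True`` (phantom inputs from ``phantom`` parameters) or
    explicit ``volume_path`` / ``shg_path`` (+ optional ``osx_path``).
    """

    simulate: bool = True
    volume_path: str = None
    shg_path: str = None
    osx_path: str = None
    seed: int = 0
    # phantom (used when simulate=True); None -> PhantomSpec defaults
    phantom: dict = field(default_factory=dict)
    # downsampling (speed knobs; spacing-preserving)
    volume_ds_factor: int = 2
    # GHT
    cone_deg: float = 25.0
    orientation_step_deg: float = 6.0
    psi_step_deg: float = 15.0
    translation_step_factor: float = 1.5   # x (downsampled) voxel spacing
    gate_deg: float = 30.0
    mag_percentile: float = 95.0
    max_edge_points: int = 2500
    n_landmarks: int = 360
    angle_bin_deg: float = 5.0
    angle_spread: int = 1
    top_k: int = 250
    refine_candidates: int = 4
    # refinement
    refine_maxfev: int = 60
    seg_keep: int = None  # None: keep every component >= 5% of the largest
    # elastic
    elastic_metric: str = "ncc"
    elastic_levels: int = 3
    elastic_iterations: int = 40
    elastic_control_spacing: float = None
    # metrics / proximity
    ssim_window: int = 7
    block_rows: int = 256

    def validate(self):
        if not self.simulate:
            if not self.volume_path or not self.shg_path:
                raise ValueError("volume_path and shg_path are required when simulate=False")
            for p in filter(None, [self.volume_path, self.shg_path, self.osx_path]):
                if not Path(p).exists():
                    raise ValueError(f"input file not found: {p}")
        if self.volume_ds_factor < 1:
            raise ValueError("volume_ds_factor must be >= 1")
        if self.elastic_metric not in ("ncc", "mattes_mi"):
            raise ValueError("elastic_metric must be 'ncc' or 'mattes_mi'")
        if self.ssim_window % 2 == 0 or self.ssim_window < 3:
            raise ValueError("ssim_window must be odd and >= 3")
        return self

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def digest(self):
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _phantom_spec(config):
    kw = dict(config.phantom)
    kw.setdefault("seed", config.seed)
    if "shape" in kw:
        kw["shape"] = tuple(kw["shape"])
    return PhantomSpec(**kw)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages, persisting artifacts under ``out_dir``.

    Artifacts: phantom inputs (NRRD/TIFF/JSON), found plane + affine (JSON),
    extracted and warped slices (TIFF), deformation field (NRRD), metrics
    (CSV), per-sample distances and summary (CSV), and a machine-readable
    ``log.json`` with package version, config hash and seed.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "config_hash": config.digest(),
           "seed": config.seed, "stages": []}
    config.to_yaml(out / "config.yaml")

    def done(stage):
        log["stages"].append(stage)
        (out / "log.json").write_text(json.dumps(log, indent=2) + "\n")

    # ---- inputs ----------------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            spec = _phantom_spec(config)
            bundle = make_phantom(spec)
            volume, shg_stack, osx_stack = bundle.volume, bundle.shg_stack, bundle.osx_stack
            write_volume(volume, out / "volume.nrrd")
            write_zstack(shg_stack, out / "shg_stack.tif")
            write_zstack(osx_stack, out / "osx_stack.tif")
            bundle.true_plane.to_json(out / "true_plane.json")
            bundle.true_warp.to_file(out / "true_warp.nrrd")
            spec.to_json(out / "phantom_spec.json")
        else:
            volume = read_volume(config.volume_path)
            shg_stack = read_zstack(config.shg_path)
            osx_stack = read_zstack(config.osx_path) if config.osx_path else None
    except Exception as exc:
        raise StageError(stage, exc) from exc
    done(stage)

    # ---- register (GHT + verification + affine refinement + extraction) --
    try:
        shg_max = max_projection(shg_stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plane, affine, info = find_cutting_plane(
                volume, shg_max,
                volume_ds_factor=config.volume_ds_factor,
                mag_percentile=config.mag_percentile,
                max_edge_points=config.max_edge_points,
                n_landmarks=config.n_landmarks,
                angle_bin_deg=config.angle_bin_deg,
                angle_spread=config.angle_spread,
                orientation_step=config.orientation_step_deg,
                psi_step=config.psi_step_deg, cone_deg=config.cone_deg,
                gate_deg=config.gate_deg,
                translation_step_factor=config.translation_step_factor,
                top_k=config.top_k, refine_candidates=config.refine_candidates,
                seg_keep=config.seg_keep, refine_maxfev=config.refine_maxfev)
        acc = info.pop("accumulator")
        order = np.argsort(acc.best_votes)[::-1][:50]
        pd.DataFrame({
            "orientation_index": order,
            "votes": acc.best_votes[order],
            "tilt_rad": acc.orientation_grid[order, 0],
            "psi_rad": acc.orientation_grid[order, 2],
        }).to_csv(out / "accumulator_peaks.csv", index=False)
        (out / "register_info.json").write_text(json.dumps(
            {k: float(v) for k, v in info.items() if np.isscalar(v)}, indent=2) + "\n")
        plane.to_json(out / "found_plane.json")
        affine.to_json(out / "affine.json")
        uct_slice, valid = extract_oblique_slice(volume, plane, shg_max.shape,
                                                 shg_max.spacing)
        write_section(uct_slice, out / "uct_slice.tif")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("register", exc) from exc
    done("register")

    # ---- elastic ---------------------------------------------------------
    try:
        grid = BSplineGrid(control_spacing=config.elastic_control_spacing,
                           levels=config.elastic_levels,
                           iterations=config.elastic_iterations)
        fld, warped = elastic_register(shg_max, uct_slice, grid=grid,
                                       metric=config.elastic_metric)
        fld.to_file(out / "deformation_field.nrrd")
        write_section(warped, out / "warped_uct_slice.tif")
    except Exception as exc:
        raise StageError("elastic", exc) from exc
    done("elastic")

    # ---- metrics ---------------------------------------------------------
    try:
        seg_fixed = segment_cortices(shg_max, keep=config.seg_keep)
        seg_moving = segment_cortices(warped, keep=config.seg_keep)
        regions = split_regions(seg_fixed, seg_moving)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = metrics_report(shg_max, warped, seg_fixed, seg_moving, fld,
                                     window=config.ssim_window, regions=regions)
        metrics.to_csv(out / "metrics.csv")
        import tifffile
        labels = np.zeros(seg_fixed.shape, np.uint8)
        labels[regions.proximal_mask.data] = 1
        labels[regions.gap_mask.data] = 2
        labels[regions.distal_mask.data] = 3
        tifffile.imwrite(str(out / "regions.tif"), labels)
    except Exception as exc:
        raise StageError("metrics", exc) from exc
    done("metrics")

    # ---- proximity -------------------------------------------------------
    try:
        rows = []
        summary_rows = []
        shg_focus = shg_stack.slices[best_focus_index(shg_stack)]
        channels = {"HA": positive_mask(warped), "collagen": positive_mask(shg_focus)}
        if osx_stack is not None:
            osx_focus = osx_stack.slices[best_focus_index(osx_stack)]
            channels["OSX"] = positive_mask(osx_focus)
        target = channels["HA"]
        samples = {}
        for name in [k for k in channels if k != "HA"]:
            q = gap_restrict(channels[name], regions)
            if not q.data.any():
                summary_rows.append({"query": name, "target": "HA", "n": 0,
                                     "median_um": np.nan, "q1_um": np.nan,
                                     "q3_um": np.nan})
                continue
            s = min_distances(q, target, block_rows=config.block_rows,
                              query_channel=name, target_channel="HA")
            samples[name] = s
            stats = s.summary()
            summary_rows.append({"query": name, "target": "HA", "n": stats["n"],
                                 "median_um": stats["median"], "q1_um": stats["q1"],
                                 "q3_um": stats["q3"]})
            for r, c, d in zip(s.rows, s.cols, s.distances):
                rows.append((name, "HA", int(r), int(c), float(d)))
        pd.DataFrame(rows, columns=["query_channel", "target_channel", "row",
                                    "col", "distance_um"]).to_csv(
            out / "distances.csv", index=False)
        comp_rows = []
        names = sorted(samples)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                stat, p = compare_groups(samples[names[i]], samples[names[j]])
                comp_rows.append({"group_a": names[i], "group_b": names[j],
                                  "statistic": stat, "p_value": p,
                                  "stars": significance_stars(p)})
        pd.DataFrame(summary_rows).to_csv(out / "proximity_summary.csv", index=False)
        pd.DataFrame(comp_rows, columns=["group_a", "group_b", "statistic",
                                         "p_value", "stars"]).to_csv(
            out / "proximity_comparisons.csv", index=False)
    except Exception as exc:
        raise StageError("proximity", exc) from exc
    done("proximity")
    return out
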