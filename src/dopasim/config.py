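"""Run configuration: a single YAML/JSON document driving any experiment.

Every physical quantity in the file carries its unit in the key name
(``vmax_uM_s``, ``domain_um``, ...), values round-trip unchanged, unknown
keys are rejected, and defaults are the dorsal-striatum parameter set with
the ventral modifications applied by ``region: VS``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dfield, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .experiments import RegionParams

__all__ = ["RunConfig", "load_config", "save_config", "run"]

EXPERIMENTS = ("run-region", "burst", "pause", "sweep", "granularity",
               "fscv-train", "nanocluster", "locclust")


@dataclass
class RunConfig:
    """Fully serialisable description of one run."""

    experiment: str = "run-region"
    region: str = "DS"
    region_overrides: dict = dfield(default_factory=dict)
    duration_s: float = 10.0
    burn_in_s: float = 5.0
    domain_um: float = 50.0
    voxel_size_um: float = 1.0
    dt_s: float = 1e-4
    snapshot_every_s: float = 0.01
    receptors: bool = False
    seed: int = 0
    seeds: dict = dfield(default_factory=dict)  # optional per-stream seeds
    output_dir: str = "runs/out"
    options: dict = dfield(default_factory=dict)  # experiment-specific knobs

    def validate(self) -> "RunConfig":
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}")
        if self.region not in ("DS", "VS", "custom"):
            raise ConfigError(f"region must be DS, VS or custom, got {self.region!r}")
        valid = {f.name for f in fields(RegionParams)}
        bad = set(self.region_overrides) - valid
        if bad:
            raise ConfigError(f"unknown region parameter keys: {sorted(bad)}")
        self.region_params()  # validates values
        if self.duration_s <= 0 or self.domain_um <= 0 or self.voxel_size_um <= 0 \
                or self.dt_s <= 0:
            raise ConfigError("durations, sizes and dt must be positive")
        bad_seed = set(self.seeds) - {"placement", "firing", "release", "burst"}
        if bad_seed:
            raise ConfigError(f"unknown seed streams: {sorted(bad_seed)}")
        return self

    def region_params(self) -> RegionParams:
        base = RegionParams.ventral if self.region == "VS" else RegionParams.dorsal
        try:
            return base(**self.region_overrides)
        except ValueError as e:
            raise ConfigError(str(e)) from e

    def resolved_seed(self):
        if self.seeds:
            d = dict(self.seeds)
            d["base"] = self.seed
            return d
        return self.seed

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file resolves to the full dorsal-striatum defaults; unknown
    top-level keys are rejected with a message naming them.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    valid = {f.name for f in fields(RunConfig)}
    bad = set(data) - valid
    if bad:
        raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
    return RunConfig(**data).validate()


def save_config(cfg: RunConfig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _native(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_native(v) for v in obj]
    return obj


def run(cfg: RunConfig) -> Path:
    """Execute a configuration; returns the run directory.

    The directory receives a copy of the resolved configuration, the
    experiment outputs (CSV traces/tables and HDF5 snapshots), and a
    manifest with content hashes so re-runs can be compared exactly.  A
    ``RUNNING`` marker is left behind if the run dies mid-way.
    """
    from . import experiments as ex
    from . import fscv as fv
    from . import io as dio
    from . import locclustering as lc
    from . import nanocluster as nc

    import time as _time

    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "RUNNING"
    marker.write_text("in progress")
    save_config(cfg, out / "config.yaml")
    params = cfg.region_params()
    seed = cfg.resolved_seed()
    opt = dict(cfg.options)
    t_start = _time.perf_counter()
    summary: dict = {"experiment": cfg.experiment, "region": params.name}
    try:
        if cfg.experiment == "run-region":
            rec = ex.run_region(
                params, cfg.duration_s, domain_um=cfg.domain_um,
                burn_in_s=cfg.burn_in_s, seed=seed, receptors=cfg.receptors,
                voxel_size=cfg.voxel_size_um, dt=cfg.dt_s,
                snapshot_every_s=cfg.snapshot_every_s, keep_final=True)
            cols = {"time_s": rec.times, "mean_nM": rec.mean_trace}
            for name, tr in rec.occ_mean.items():
                cols[f"occ_{name}_mean"] = tr
            dio.save_trace(out / "trace.csv", cols)
            dio.save_trace(out / "percentiles.csv",
                           {"percentile": rec.stats.percentiles,
                            "concentration_nM": rec.stats.values})
            dio.save_field(out / "final_field.h5", rec.final_field,
                           cfg.voxel_size_um, rec.times[-1])
            summary.update(mean_nM=rec.stats.spatial_mean,
                           p50_nM=rec.stats.p50, p99_5_nM=rec.stats.p99_5,
                           focality=rec.stats.focality)
        elif cfg.experiment == "burst":
            res = ex.burst_experiment(
                params, int(opt.pop("n_pulses", 6)),
                float(opt.pop("rate_hz", 20.0)), domain_um=cfg.domain_um,
                equilibrate_s=float(opt.pop("equilibrate_s", 2.0)),
                seed=seed, dt=cfg.dt_s, **opt)
            dio.save_trace(out / "cube_trace.csv",
                           {"time_s": res.cube_times,
                            "cube_mean_nM": res.cube_mean_trace})
            summary.update(peak_cube_mean_nM=res.peak_cube_mean_nM,
                           spill_ratio_end=res.spill_ratio_end,
                           spill_ratio_100ms=res.spill_ratio_100ms)
        elif cfg.experiment == "pause":
            res = ex.pause_experiment(
                params, float(opt.pop("pause_s", 1.0)),
                equilibrate_s=float(opt.pop("equilibrate_s", 10.0)),
                domain_um=cfg.domain_um, seed=seed, dt=cfg.dt_s, **opt)
            dio.save_trace(out / "pause_trace.csv",
                           {"time_s": res.times, "mean_nM": res.mean_trace,
                            "occ_D1_probe": res.d1_probe,
                            "occ_D2_probe": res.d2_probe})
            summary.update(d2_baseline=res.d2_baseline,
                           d2_pause_end=res.d2_pause_end)
        elif cfg.experiment == "sweep":
            axis = opt.pop("axis", "vmax")
            grid = opt.pop("grid", [3.0, 6.0, 9.0])
            df = ex.sweep(params, axis, grid, domain_um=cfg.domain_um,
                          duration_s=cfg.duration_s, burn_in_s=cfg.burn_in_s,
                          seed=seed, dt=cfg.dt_s, **opt)
            df.to_csv(out / "sweep.csv", index=False)
            summary.update(axis=axis, n_points=len(df))
        elif cfg.experiment == "granularity":
            res = ex.granularity_check(
                params, tuple(opt.pop("voxel_sizes", (0.5, 1.0))),
                domain_um=cfg.domain_um, duration_s=cfg.duration_s,
                burn_in_s=cfg.burn_in_s, seed=seed, dt=cfg.dt_s, **opt)
            rows = {"percentile": res.percentiles}
            for v, c in res.curves.items():
                rows[f"conc_nM_{v}um"] = c
            dio.save_trace(out / "granularity.csv", rows)
            summary.update(median_abs_deviation={
                str(k): v for k, v in res.median_abs_deviation.items()})
        elif cfg.experiment == "fscv-train":
            res = fv.stim_train_experiment(
                params, n_pulses=int(opt.pop("n_pulses", 120)),
                rate_hz=float(opt.pop("rate_hz", 60.0)),
                domain_um=cfg.domain_um, seed=seed, dt=cfg.dt_s, **opt)
            dio.save_trace(out / "fscv_raw.csv",
                           {"time_s": res.times, "raw_nM": res.raw})
            dio.save_trace(out / "fscv_convolved.csv",
                           {"time_s": res.scan_times,
                            "convolved_nM": res.convolved})
            summary.update(peak_raw_nM=res.peak_raw_nM,
                           peak_convolved_nM=res.peak_convolved_nM)
        elif cfg.experiment == "nanocluster":
            gran_nm = float(opt.pop("granularity_nm", 20.0))
            diameter = opt.pop("diameter_nm", "dispersed")
            mode = opt.pop("mode", "steady")
            surf = nc.VaricositySurface(granularity_um=gran_nm * 1e-3)
            layout = nc.build_layout(surf, diameter, seed=cfg.seed, **opt)
            if mode == "steady":
                res = nc.steady_drive_run(layout, duration_s=cfg.duration_s)
            elif mode == "clearance":
                res = nc.clearance_run(layout)
                summary.update(time_to_target_s=res.time_to_target_s)
            else:
                raise ConfigError("nanocluster mode must be steady or clearance")
            dio.save_trace(out / "nano_trace.csv",
                           {"time_s": res.times, "mean_nM": res.mean_trace,
                            "centre_nM": res.centre_trace})
            dio.save_field(out / "nano_final.h5", res.final_field,
                           surf.granularity_um, res.times[-1])
            summary.update(final_mean_nM=float(res.mean_trace[-1]))
        elif cfg.experiment == "locclust":
            import pandas as pd

            paths = opt.pop("tables", [])
            radius = float(opt.pop("radius_nm", 40.0))
            min_pts = int(opt.pop("min_points", 40))
            scan = opt.pop("scan", False)
            labels = opt.pop("region_labels", [])
            tables = [lc.read_localisations(p, **opt) for p in paths]
            rows = [{"table": str(p),
                     "percent_clustered": lc.percent_clustered(t, radius, min_pts)}
                    for p, t in zip(paths, tables)]
            pd.DataFrame(rows).to_csv(out / "locclust.csv", index=False)
            summary.update(n_tables=len(rows))
            if scan and tables:
                by_region: dict = {}
                for i, t in enumerate(tables):
                    region = labels[i] if i < len(labels) else "all"
                    by_region.setdefault(region, []).append(t)
                radii = np.arange(10.0, 201.0, 10.0)
                mins = np.arange(10, 201, 10)
                res = lc.parameter_scan(by_region, radii, mins)
                res.to_frame().to_csv(out / "locclust_scan.csv", index=False)
                if len(by_region) == 2:
                    a, b = list(by_region)
                    summary.update(scan_regions=[a, b],
                                   mean_difference=float(res.difference.mean()))
        summary["elapsed_s"] = round(_time.perf_counter() - t_start, 3)
        (out / "summary.json").write_text(
            json.dumps(_native(summary), indent=2, sort_keys=True))
        manifest = {p.name: dio.file_sha256(p)
                    for p in sorted(out.iterdir())
                    if p.is_file() and p.name not in ("RUNNING", "manifest.json")}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        marker.write_text("failed")
        raise
    marker.unlink()
    return out
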