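"""Config-driven runs: stage orchestration, tidy outputs, logging.

A run is described by a YAML-serializable :class:`RunConfig`: a seed, an
output directory, and a list of stages executed in order.  Stages share
an artifact namespace (e.g. a simulation stage publishes images a
comparison stage consumes).  Per-sample failures (missing files,
malformed tables) become error records in the report; the batch
continues.  Every run writes its resolved config beside the outputs so
a rerun reproduces them bit-for-bit given the same seeds.

Outputs are tidy long-format CSVs (one row per sample per metric) so
group plots and tests can be regenerated; every test row names its test
and sample sizes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, branchmetrics, kymo, orientation, syndata
from .errors import ConfigError
from .images import load_pixel_image
from .roi import ROIGrid


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "arborquant_out"
    stages: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "stages" not in raw:
            raise ConfigError(f"config {path} must define a 'stages' list")
        return cls(seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "arborquant_out")),
                   stages=list(raw["stages"]))

    def to_dict(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, "stages": self.stages}


@dataclass
class ReportBundle:
    results: dict = field(default_factory=dict)   # name -> DataFrame
    tests: pd.DataFrame | None = None
    errors: list = field(default_factory=list)
    log: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)  # in-memory stage outputs

    def add_error(self, stage, item, message):
        self.errors.append({"stage": stage, "item": str(item), "error": message})

    def write(self, out_dir, config: RunConfig | None = None):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        if self.tests is not None and len(self.tests):
            self.tests.to_csv(out / "tests.csv", index=False)
        if self.errors:
            pd.DataFrame(self.errors).to_csv(out / "errors.csv", index=False)
        with open(out / "run_log.jsonl", "w") as fh:
            for line in self.log:
                fh.write(json.dumps({"msg": line}) + "\n")
        if config is not None:
            with open(out / "resolved_config.yaml", "w") as fh:
                yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _load_group_images(params, bundle, stage_name):
    """Images either from a simulation artifact or from TIFF manifests."""
    if "from_stage" in params:
        return bundle.artifacts[params["from_stage"]]
    groups = {}
    for g, paths in params["images"].items():
        imgs = []
        for p in paths:
            try:
                imgs.append(load_pixel_image(p))
            except (FileNotFoundError, OSError, ConfigError) as e:
                bundle.add_error(stage_name, p, str(e))
        groups[g] = imgs
    return groups


def _stage_simulate_arbors(params, cfg, bundle):
    name = params.get("name", "simulate_arbors")
    out = {}
    truth_rows = []
    for g, gspec in params["groups"].items():
        n_images = int(gspec.pop("n_images", 5))
        imgs = []
        for i in range(n_images):
            spec = syndata.SynthArborSpec(
                **gspec, seed=int(np.random.default_rng([cfg.seed, zlib.crc32(g.encode()) % 2**16, i]).integers(2**31))
            )
            img, gt = syndata.generate_arbor_image(spec)
            imgs.append(img)
            df = gt.segments.assign(group=g, image=i)
            truth_rows.append(df)
        gspec["n_images"] = n_images
        out[g] = imgs
    bundle.artifacts[name] = out
    if truth_rows:
        bundle.results[f"{name}_ground_truth"] = pd.concat(truth_rows, ignore_index=True)
    bundle.log.append(f"{name}: simulated {sum(len(v) for v in out.values())} images")


def _stage_orientation_compare(params, cfg, bundle):
    name = params.get("name", "orientation_compare")
    groups = _load_group_images(params, bundle, name)
    if len(groups) != 2:
        raise ConfigError("orientation_compare needs exactly two groups")
    normalized = bool(params.get("normalized", True))
    rng = tuple(params.get("angle_range", (-50.5, -20.5)))
    profs = {}
    for g, imgs in groups.items():
        plist = []
        for i, im in enumerate(imgs):
            try:
                p = orientation.orientation_histogram(im)
                plist.append(orientation.normalize_profile(p) if normalized else p)
            except Exception as e:  # noqa: BLE001 - per-sample isolation
                bundle.add_error(name, f"{g}[{i}]", str(e))
        profs[g] = plist
    (ga, pa), (gb, pb) = profs.items()
    cmp_ = orientation.compare_auc(pa, pb, rng)
    row = cmp_.to_row()
    row.update(group_a=ga, group_b=gb, metric="orientation_auc")
    bundle.results[name] = pd.DataFrame([row])
    bundle.log.append(f"{name}: AUC {ga} vs {gb} over {rng}: p={cmp_.p:.4g}")
    return pd.DataFrame([dict(metric=f"{name}:auc", test="welch_t",
                              statistic=cmp_.t, p=cmp_.p,
                              n=f"{len(pa)}/{len(pb)}")])


def _stage_density_compare(params, cfg, bundle):
    name = params.get("name", "density_compare")
    groups = _load_group_images(params, bundle, name)
    grid_params = params.get("grid")
    frames = {}
    for g, imgs in groups.items():
        rows = []
        for i, im in enumerate(imgs):
            grid = (ROIGrid(**grid_params) if grid_params
                    else ROIGrid.standard_for_image(im.shape, im.px_size_um))
            try:
                prof = branchmetrics.count_branch_crossings(im, grid)
                rows.append(prof.to_frame(embryo_id=i))
            except Exception as e:  # noqa: BLE001
                bundle.add_error(name, f"{g}[{i}]", str(e))
        frames[g] = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        bundle.results[f"{name}_{g}"] = frames[g]
    if len(frames) == 2:
        (ga, fa), (gb, fb) = frames.items()
        cmp_ = branchmetrics.compare_density(fa, fb, params.get("roi_subset"))
        bundle.log.append(f"{name}: density AUC {ga} vs {gb}: p={cmp_.p:.4g}")
        return pd.DataFrame([dict(metric=f"{name}:auc", test="welch_t",
                                  statistic=cmp_.t, p=cmp_.p,
                                  n=f"{fa.embryo_id.nunique()}/{fb.embryo_id.nunique()}")])
    return None


def _stage_event_stats(params, cfg, bundle):
    name = params.get("name", "event_stats")
    rows = []
    for g, src in params["groups"].items():
        try:
            if isinstance(src, str):
                events = pd.read_csv(src)
            else:
                spec = syndata.SynthEventTableSpec(**src, seed=cfg.seed)
                events = syndata.generate_event_table(spec)
            dur = float(params.get("duration_h", 2.0))
            rates = branchmetrics.initiation_rate(events, dur)["per_type"]
            losses = branchmetrics.loss_ratio(events)["per_type"]
            for btype in rates.index:
                rows.append(dict(group=g, type=btype,
                                 initiation_rate_per_h=rates[btype],
                                 loss_ratio=losses.get(btype, np.nan)))
        except (FileNotFoundError, OSError, KeyError, ConfigError) as e:
            bundle.add_error(name, g, str(e))
    bundle.results[name] = pd.DataFrame(rows)
    bundle.log.append(f"{name}: {len(rows)} group×type rows")


def _stage_behavior_tank(params, cfg, bundle):
    name = params.get("name", "behavior_tank")
    rows = []
    for g, src in params["groups"].items():
        if isinstance(src, dict):  # simulate n_fish sessions
            n_fish = int(src.pop("n_fish", 10))
            for i in range(n_fish):
                seed = int(np.random.default_rng([cfg.seed, zlib.crc32(g.encode()) % 2**16, i]).integers(2**31))
                spec = syndata.SynthTrajectorySpec(**src, seed=seed)
                df, _ = syndata.generate_trajectory(spec)
                traj = behavior.Trajectory(df, spec.fps, *spec.tank_size_cm)
                row = behavior.tank_session(traj).to_row()
                row.update(group=g, fish=i)
                rows.append(row)
            src["n_fish"] = n_fish
        else:  # list of trajectory CSVs
            fps = float(params.get("fps", 10.0))
            tank = params.get("tank_size_cm", (30.0, 20.0))
            for p in src:
                try:
                    df = pd.read_csv(p)
                    traj = behavior.Trajectory(df, fps, *tank)
                    row = behavior.tank_session(traj).to_row()
                    row.update(group=g, fish=Path(p).stem)
                    rows.append(row)
                except (FileNotFoundError, OSError, ConfigError, KeyError) as e:
                    bundle.add_error(name, p, str(e))
    sessions = pd.DataFrame(rows)
    bundle.results[name] = sessions
    if sessions.empty or sessions.group.nunique() != 2:
        return None
    stats_out = behavior.group_session_stats(sessions)
    bundle.log.append(f"{name}: {len(sessions)} sessions in {sessions.group.nunique()} groups")
    return stats_out["tests"].assign(metric=lambda d: name + ":" + d.metric)


_STAGES = {
    "simulate_arbors": _stage_simulate_arbors,
    "orientation_compare": _stage_orientation_compare,
    "density_compare": _stage_density_compare,
    "event_stats": _stage_event_stats,
    "behavior_tank": _stage_behavior_tank,
}


def run(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute all stages of a run; returns the report bundle.

    Deterministic given the config seed.  Stage-level configuration
    errors abort the run; per-sample failures are recorded and skipped.
    """
    bundle = ReportBundle()
    test_frames = []
    for stage in config.stages:
        stage = dict(stage)
        kind = stage.pop("kind", None)
        if kind not in _STAGES:
            raise ConfigError(f"unknown stage kind {kind!r}")
        res = _STAGES[kind](stage, config, bundle)
        if isinstance(res, pd.DataFrame):
            test_frames.append(res)
    if test_frames:
        bundle.tests = pd.concat(test_frames, ignore_index=True)
    if write:
        bundle.write(config.out_dir, config)
    return bundle
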