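"""Pipeline orchestration: staged runs with a reproducible manifest.

Stages run in dependency order — ``generate`` (synthetic cohort + flexion
task) → ``rhythm`` (per-subject rhythm extraction, healthy means) →
``cor-search`` (441-candidate COR grid on the flexion task) → ``simulate``
(per-patient before/after reports) → ``cohort`` (aggregation).  Partial
stage lists resume from existing outputs; a missing upstream output raises
:class:`DependencyError`.  Every run directory holds exactly one
``manifest.json`` recording the config hash, seed, package version, stage
outputs, solver residual summary and wall time.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, DependencyError
from .interventions import (
    CorGridSpec,
    InterventionReport,
    cohort_report,
    cor_grid_search,
    simulate_combined,
    simulate_reconstruction,
    simulate_rehabilitation,
)
from .kinematics import read_markers, write_markers
from .loading import SpineLoadingModel
from .rhythm import (
    JOINTS,
    SegmentAngles,
    SpineRhythm,
    compute_rhythm,
    markers_to_segment_angles,
    mean_rhythm,
    read_rhythm_csv,
    write_rhythm_csv,
)
from .kinematics import extract_cycle
from .skeleton import CorOffset, build_default_model
from .synthetic import (
    TEMPLATES,
    SubjectProfile,
    generate_cohort,
    generate_flexion_task,
    generate_subject,
)

STAGES = ("generate", "rhythm", "cor-search", "simulate", "cohort")
INTERVENTIONS = ("rehabilitation", "reconstruction", "combined")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_healthy": 26,
        "n_ldh": 7,
        "rhythm_profile_sd": 0.02,
        "rhythm_jitter_sd": 0.0,
        "marker_noise_sd": 0.0,
    },
    "activities": ["level_walking", "stair_climbing"],
    "interventions": ["rehabilitation", "reconstruction"],
    "model": {"config": None},
    "solver": {"axes": "sagittal", "inertial": False},
    "grid": {
        "ap": [-10.0, 10.0],
        "si": [-10.0, 10.0],
        "step": 1.0,
        "flexion_amplitude_deg": 45.0,
        "flexion_frames": 21,
    },
    "cycle": {"leg": "L", "index": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text())
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError("pipeline config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema checks; error messages name the offending field."""
    co = cfg.get("cohort", {})
    for fld in ("n_healthy", "n_ldh"):
        if int(co.get(fld, 0)) < 0:
            raise ConfigError(f"cohort.{fld} must be >= 0")
    for fld in ("rhythm_profile_sd", "rhythm_jitter_sd", "marker_noise_sd"):
        if float(co.get(fld, 0.0)) < 0:
            raise ConfigError(f"cohort.{fld} must be >= 0")
    for act in cfg.get("activities", []):
        if act not in TEMPLATES:
            raise ConfigError(f"activities: unknown activity {act!r}")
    for iv in cfg.get("interventions", []):
        if iv not in INTERVENTIONS:
            raise ConfigError(f"interventions: unknown intervention {iv!r}")
    grid = cfg.get("grid", {})
    if float(grid.get("step", 1.0)) <= 0:
        raise ConfigError("grid.step must be > 0")
    if float(grid.get("flexion_amplitude_deg", 45.0)) <= 0:
        raise ConfigError("grid.flexion_amplitude_deg must be > 0")
    if cfg.get("solver", {}).get("axes", "sagittal") not in ("sagittal", "3d"):
        raise ConfigError("solver.axes must be 'sagittal' or '3d'")


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)       # stage -> list of paths
    residuals: dict = field(default_factory=dict)    # label -> max residual
    wall_time_s: float = 0.0

    def write(self, out_dir: Path) -> Path:
        p = Path(out_dir) / "manifest.json"
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": {k: [str(x) for x in v] for k, v in self.stages.items()},
            "residuals": self.residuals,
            "wall_time_s": round(self.wall_time_s, 3),
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return p


# ---------------------------------------------------------------------------
# small angle-series CSV helpers (frame, pelvis, 6 joints; radians)


def write_angles_csv(angles: SegmentAngles, path: Path) -> Path:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"# rate_hz={angles.rate:g}"])
        w.writerow(["frame", "pelvis", *JOINTS])
        for i in range(angles.n_frames):
            w.writerow(
                [i, f"{angles.pelvis[i]:.12g}", *[f"{v:.12g}" for v in angles.joints[i]]]
            )
    return path


def read_angles_csv(path: Path) -> SegmentAngles:
    with open(path, newline="") as fh:
        first = fh.readline()
        rate = 100.0
        if first.startswith("#"):
            rate = float(first.split("rate_hz=")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return SegmentAngles(
        df["pelvis"].to_numpy(), df[list(JOINTS)].to_numpy(), rate
    )


# ---------------------------------------------------------------------------
# stages


def _subject_paths(out: Path, sid: str, activity: str) -> dict[str, Path]:
    return {
        "trc": out / "data" / f"{sid}_{activity}.trc",
        "truth": out / "data" / f"{sid}_{activity}_truth.json",
        "rhythm": out / "rhythms" / f"{sid}_{activity}.csv",
    }


def _stage_generate(cfg: dict, out: Path) -> list[Path]:
    co = cfg["cohort"]
    (out / "data").mkdir(parents=True, exist_ok=True)
    (out / "tasks").mkdir(parents=True, exist_ok=True)
    profiles = generate_cohort(
        n_healthy=int(co["n_healthy"]), n_ldh=int(co["n_ldh"]), seed=int(cfg["seed"]),
        rhythm_profile_sd=float(co["rhythm_profile_sd"]),
        rhythm_jitter_sd=float(co["rhythm_jitter_sd"]),
        marker_noise_sd=float(co["marker_noise_sd"]),
    )
    written: list[Path] = []
    rows = []
    for prof in profiles:
        for act in cfg["activities"]:
            sub = generate_subject(prof, TEMPLATES[act]())
            paths = _subject_paths(out, prof.subject_id, act)
            write_markers(sub.markers, paths["trc"], dialect="trc", events=sub.events)
            truth = {
                "subject_id": prof.subject_id,
                "group": prof.group,
                "mass": prof.mass,
                "height": prof.height,
                "rhythm": [float(v) for v in prof.rhythm],
                "seed": int(prof.seed),
                "baseline": list(sub.baseline),
                "activity": act,
            }
            paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
            written += [paths["trc"], paths["truth"]]
        rows.append(
            {"subject_id": prof.subject_id, "group": prof.group,
             "mass": prof.mass, "height": prof.height, "seed": int(prof.seed)}
        )
    pd.DataFrame(rows).to_csv(out / "data" / "cohort_manifest.csv", index=False)
    written.append(out / "data" / "cohort_manifest.csv")

    grid = cfg["grid"]
    flex = generate_flexion_task(
        float(grid["flexion_amplitude_deg"]), n_frames=int(grid["flexion_frames"])
    )
    written.append(write_angles_csv(flex, out / "tasks" / "flexion.csv"))
    return written


def _iter_subjects(out: Path) -> list[dict]:
    manifest = out / "data" / "cohort_manifest.csv"
    if not manifest.exists():
        raise DependencyError("run the 'generate' stage first: cohort manifest missing")
    return pd.read_csv(manifest).to_dict("records")


def _stage_rhythm(cfg: dict, out: Path) -> list[Path]:
    (out / "rhythms").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    healthy: dict[str, list[SpineRhythm]] = {a: [] for a in cfg["activities"]}
    for row in _iter_subjects(out):
        sid = row["subject_id"]
        for act in cfg["activities"]:
            paths = _subject_paths(out, sid, act)
            if not paths["trc"].exists():
                raise DependencyError(f"missing generated markers {paths['trc']}")
            markers, events = read_markers(paths["trc"], dialect="trc")
            truth = json.loads(paths["truth"].read_text())
            angles = markers_to_segment_angles(markers, baseline=tuple(truth["baseline"]))
            cyc = SegmentAngles(
                extract_cycle(angles.pelvis, events, leg=cfg["cycle"]["leg"],
                              cycle=int(cfg["cycle"]["index"])),
                extract_cycle(angles.joints, events, leg=cfg["cycle"]["leg"],
                              cycle=int(cfg["cycle"]["index"])),
                angles.rate,
            )
            r = compute_rhythm(cyc)
            written.append(write_rhythm_csv(r, paths["rhythm"]))
            if row["group"] == "healthy":
                healthy[act].append(r)
    for act, rs in healthy.items():
        if rs:
            written.append(
                write_rhythm_csv(mean_rhythm(rs), out / "rhythms" / f"healthy_mean_{act}.csv")
            )
    return written


def _stage_cor_search(cfg: dict, out: Path) -> list[Path]:
    flex_path = out / "tasks" / "flexion.csv"
    if not flex_path.exists():
        raise DependencyError("run the 'generate' stage first: flexion task missing")
    angles = read_angles_csv(flex_path)
    grid_cfg = cfg["grid"]
    grid = CorGridSpec(
        ap_range=tuple(grid_cfg["ap"]), si_range=tuple(grid_cfg["si"]),
        step=float(grid_cfg["step"]),
        flexion_amplitude_deg=float(grid_cfg["flexion_amplitude_deg"]),
        flexion_frames=int(grid_cfg["flexion_frames"]),
    )
    model = build_default_model(cfg["model"]["config"])
    result = cor_grid_search(model, grid, angles=angles, axes=cfg["solver"]["axes"])
    (out / "cor").mkdir(parents=True, exist_ok=True)
    scores = out / "cor" / "scores.csv"
    result.table.to_csv(scores, index=False)
    sel = out / "cor" / "selected.json"
    sel.write_text(json.dumps(
        {"ap": result.selected.ap, "si": result.selected.si,
         "level": result.selected.level,
         "score": result.selected_score, "default_score": result.default_score},
        indent=2, sort_keys=True) + "\n")
    return [scores, sel]


def _load_selected_offset(out: Path) -> CorOffset:
    sel = out / "cor" / "selected.json"
    if not sel.exists():
        raise DependencyError("run the 'cor-search' stage first: selection missing")
    d = json.loads(sel.read_text())
    return CorOffset(ap=d["ap"], si=d["si"], level=d["level"])


def _stage_simulate(cfg: dict, out: Path, residuals: dict) -> list[Path]:
    written: list[Path] = []
    axes = cfg["solver"]["axes"]
    need_recon = any(k in cfg["interventions"] for k in ("reconstruction", "combined"))
    offset = _load_selected_offset(out) if need_recon else None
    for row in _iter_subjects(out):
        if row["group"] != "ldh":
            continue
        sid = row["subject_id"]
        for act in cfg["activities"]:
            paths = _subject_paths(out, sid, act)
            healthy_path = out / "rhythms" / f"healthy_mean_{act}.csv"
            if not healthy_path.exists():
                raise DependencyError("run the 'rhythm' stage first: healthy mean missing")
            target = read_rhythm_csv(healthy_path)
            markers, events = read_markers(paths["trc"], dialect="trc")
            truth = json.loads(paths["truth"].read_text())
            skeleton = build_default_model(cfg["model"]["config"], body_mass=truth["mass"])
            lmodel = SpineLoadingModel.from_markers(
                markers, events, baseline=tuple(truth["baseline"]),
                leg=cfg["cycle"]["leg"], cycle=int(cfg["cycle"]["index"]),
                skeleton=skeleton, activity=act,
            )
            before = lmodel.fit(axes=axes, inertial=bool(cfg["solver"]["inertial"]))
            residuals[f"{sid}/{act}"] = before.max_residual
            sim_dir = out / "sim" / sid / act
            for kind in cfg["interventions"]:
                if kind == "rehabilitation":
                    rep = simulate_rehabilitation(
                        lmodel.angles, target, skeleton, activity=act,
                        axes=axes, before=before,
                    )
                elif kind == "reconstruction":
                    rep = simulate_reconstruction(
                        lmodel.angles, offset, skeleton, activity=act,
                        axes=axes, before=before,
                    )
                else:
                    rep = simulate_combined(
                        lmodel.angles, target, offset, skeleton, activity=act, axes=axes
                    )
                written += rep.to_csv(sim_dir, stem=sid)
    return written


def _read_report(sim_dir: Path, sid: str, kind: str, activity: str) -> InterventionReport:
    def _read_curve(name: str) -> pd.DataFrame:
        p = sim_dir / f"{sid}_{kind}_forces_{name}.csv"
        if not p.exists():
            raise DependencyError(f"run the 'simulate' stage first: {p} missing")
        return pd.read_csv(p, index_col="percent")

    mma = pd.read_csv(sim_dir / f"{sid}_{kind}_mma.csv", index_col="group")
    return InterventionReport(
        activity=activity, kind=kind,
        before_forces_bw=_read_curve("before"),
        after_forces_bw=_read_curve("after"),
        mma_before=mma["before"], mma_after=mma["after"],
    )


def _stage_cohort(cfg: dict, out: Path) -> list[Path]:
    written: list[Path] = []
    for act in cfg["activities"]:
        for kind in cfg["interventions"]:
            reports = []
            for row in _iter_subjects(out):
                if row["group"] != "ldh":
                    continue
                sim_dir = out / "sim" / row["subject_id"] / act
                reports.append(_read_report(sim_dir, row["subject_id"], kind, act))
            if reports:
                agg = cohort_report(reports)
                written += agg.to_csv(out / "cohort", stem=act)
    return written


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: list[str] | None = None,
    out_dir: str | Path = "spineload_run",
    dry_run: bool = False,
) -> RunManifest:
    """Execute the requested stages in dependency order and write the
    manifest.  With ``dry_run``, print the stage plan and do nothing."""
    cfg = config if isinstance(config, dict) else load_config(config)
    validate_config(cfg)
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; stages are {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    if dry_run:
        print("plan:", " -> ".join(ordered))
        return RunManifest(config_hash(cfg), int(cfg["seed"]), __version__)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = RunManifest(config_hash(cfg), int(cfg["seed"]), __version__)
    residuals: dict[str, float] = {}
    runners = {
        "generate": lambda: _stage_generate(cfg, out),
        "rhythm": lambda: _stage_rhythm(cfg, out),
        "cor-search": lambda: _stage_cor_search(cfg, out),
        "simulate": lambda: _stage_simulate(cfg, out, residuals),
        "cohort": lambda: _stage_cohort(cfg, out),
    }
    for s in ordered:
        manifest.stages[s] = runners[s]()
    manifest.residuals = {k: float(v) for k, v in residuals.items()}
    manifest.wall_time_s = time.time() - t0
    manifest.write(out)
    return manifest
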