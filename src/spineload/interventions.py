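"""Simulated interventions: rhythm rehabilitation and COR reconstruction.

Rehabilitation replaces the subject's spine rhythm with a reference
(healthy-mean) rhythm, leaving the total trunk motion and the mechanical
model untouched.  Reconstruction relocates the L5S1 joint center by a
sagittal offset chosen by an exhaustive grid search (±10 mm
anterior–posterior × ±10 mm superior–inferior in 1 mm steps, 441
candidates) over a trunk-flexion task driven by the default uniform rhythm;
candidates are scored by the mean summed body-weight-normalized joint
resultant force at L3L4 + L4L5 + L5S1.  Both interventions report 101-point
improvement curves (before − after, BW) for the five lumbar joints and
before/after/delta maximum muscle activities for the 17 groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AggregationError, InfeasibleError
from .kinematics import CYCLE_POINTS
from .loading import SpineLoadingModel, SpineLoadingResults
from .recruit import net_loads, solve_cycle
from .rhythm import LUMBAR_JOINTS, SegmentAngles, SpineRhythm, substitute_rhythm
from .skeleton import CorOffset, SpineModel, apply_cor_offset, pose_model
from .synthetic import generate_flexion_task

logger = logging.getLogger(__name__)

#: joints entering the COR-search score
SCORE_JOINTS = ("L3L4", "L4L5", "L5S1")


@dataclass
class CorGridSpec:
    """The candidate COR offset grid and its driving flexion task."""

    ap_range: tuple[float, float] = (-10.0, 10.0)   # mm, anterior positive
    si_range: tuple[float, float] = (-10.0, 10.0)   # mm, superior positive
    step: float = 1.0                               # mm
    level: str = "L5S1"
    flexion_amplitude_deg: float = 45.0
    flexion_frames: int = 21

    def offsets(self) -> list[CorOffset]:
        aps = np.arange(self.ap_range[0], self.ap_range[1] + 0.5 * self.step, self.step)
        sis = np.arange(self.si_range[0], self.si_range[1] + 0.5 * self.step, self.step)
        return [
            CorOffset(ap=float(a), si=float(s), level=self.level)
            for a in aps for s in sis
        ]


@dataclass
class CorSearchResult:
    """Full score map plus the selected offset."""

    table: pd.DataFrame          # ap, si, score, per-joint mean BW columns
    selected: CorOffset
    default_score: float

    @property
    def selected_score(self) -> float:
        m = (self.table["ap"] == self.selected.ap) & (self.table["si"] == self.selected.si)
        return float(self.table.loc[m, "score"].iloc[0])


def _score_candidate(
    model: SpineModel, angles: SegmentAngles, axes: str
) -> tuple[float, dict[str, float]]:
    posed = pose_model(model, angles)
    net = net_loads(posed)
    sol = solve_cycle(posed, net, axes=axes)
    per_joint = {
        j: float(sol.reaction_bw[:, model.joint_index(j)].mean()) for j in SCORE_JOINTS
    }
    return float(sum(per_joint.values())), per_joint


def cor_grid_search(
    model: SpineModel,
    grid: CorGridSpec | None = None,
    angles: SegmentAngles | None = None,
    axes: str = "sagittal",
) -> CorSearchResult:
    """Exhaustively score every candidate COR offset on the flexion task.

    Infeasible candidates are scored +inf and logged, never fatal.  The
    selected offset attains the minimal score; ties break by smallest
    Euclidean offset, then lexicographically on (ap, si).
    """
    grid = grid or CorGridSpec()
    if angles is None:
        angles = generate_flexion_task(
            grid.flexion_amplitude_deg, n_frames=grid.flexion_frames
        )
    rows = []
    for off in grid.offsets():
        try:
            score, per_joint = _score_candidate(apply_cor_offset(model, off), angles, axes)
        except InfeasibleError as exc:
            logger.info("COR candidate (%+g, %+g) infeasible: %s", off.ap, off.si, exc)
            score, per_joint = np.inf, {j: np.nan for j in SCORE_JOINTS}
        rows.append(
            {"ap": off.ap, "si": off.si, "score": score}
            | {f"mean_bw_{j}": v for j, v in per_joint.items()}
        )
    table = pd.DataFrame(rows)
    if not np.isfinite(table["score"]).any():
        raise InfeasibleError("every COR candidate was infeasible")

    key = list(
        zip(table["score"], table["ap"] ** 2 + table["si"] ** 2, table["ap"], table["si"])
    )
    best = int(min(range(len(key)), key=key.__getitem__))
    selected = CorOffset(
        ap=float(table.at[best, "ap"]), si=float(table.at[best, "si"]), level=grid.level
    )
    at_zero = (table["ap"] == 0.0) & (table["si"] == 0.0)
    if at_zero.any():
        default_score = float(table.loc[at_zero, "score"].iloc[0])
    else:
        default_score, _ = _score_candidate(model, angles, axes)
    return CorSearchResult(table, selected, default_score)


# ---------------------------------------------------------------------------
# intervention reports


@dataclass
class InterventionReport:
    """Before/after loading outcomes for one subject, one activity.

    ``improvement = before − after`` pointwise on the 101-point cycle grid
    (positive where the intervention lowered the load); MMAs likewise.
    """

    activity: str
    kind: str                          # rehabilitation | reconstruction | combined
    before_forces_bw: pd.DataFrame     # (101, 5)
    after_forces_bw: pd.DataFrame
    mma_before: pd.Series              # (17,)
    mma_after: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for df in (self.before_forces_bw, self.after_forces_bw):
            if df.shape != (CYCLE_POINTS, len(LUMBAR_JOINTS)):
                raise AggregationError(
                    f"force curves must be ({CYCLE_POINTS}, {len(LUMBAR_JOINTS)}), "
                    f"got {df.shape}"
                )
        if not (np.isfinite(self.before_forces_bw.to_numpy()).all()
                and np.isfinite(self.after_forces_bw.to_numpy()).all()):
            raise AggregationError("force curves contain non-finite values")

    @property
    def improvement(self) -> pd.DataFrame:
        return self.before_forces_bw - self.after_forces_bw

    @property
    def mma_delta(self) -> pd.Series:
        return (self.mma_before - self.mma_after).rename("delta_MMA")

    def to_csv(self, out_dir: str | Path, stem: str = "report") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in (
            ("before", self.before_forces_bw),
            ("after", self.after_forces_bw),
            ("improvement", self.improvement),
        ):
            p = out_dir / f"{stem}_{self.kind}_forces_{name}.csv"
            df.to_csv(p)
            paths.append(p)
        mma = pd.DataFrame(
            {"before": self.mma_before, "after": self.mma_after, "delta": self.mma_delta}
        ).rename_axis("group")
        p = out_dir / f"{stem}_{self.kind}_mma.csv"
        mma.to_csv(p)
        paths.append(p)
        return paths


def _report_from_results(
    before: SpineLoadingResults,
    after: SpineLoadingResults,
    kind: str,
    activity: str | None,
    meta: dict | None = None,
) -> InterventionReport:
    return InterventionReport(
        activity=activity or before.model.activity or "<unlabelled>",
        kind=kind,
        before_forces_bw=before.joint_forces_bw,
        after_forces_bw=after.joint_forces_bw,
        mma_before=before.mma,
        mma_after=after.mma,
        meta=meta or {},
    )


def simulate_rehabilitation(
    angles: SegmentAngles,
    target: SpineRhythm,
    model: SpineModel,
    activity: str | None = None,
    axes: str = "sagittal",
    before: SpineLoadingResults | None = None,
) -> InterventionReport:
    """Solve loads before and after substituting the target rhythm; the
    mechanical model is unchanged."""
    if before is None:
        before = SpineLoadingModel(angles, model, activity=activity).fit(axes=axes)
    after_angles = substitute_rhythm(angles, target)
    after = SpineLoadingModel(after_angles, model, activity=activity).fit(axes=axes)
    return _report_from_results(before, after, "rehabilitation", activity)


def simulate_reconstruction(
    angles: SegmentAngles,
    offset: CorOffset,
    model: SpineModel,
    activity: str | None = None,
    axes: str = "sagittal",
    before: SpineLoadingResults | None = None,
) -> InterventionReport:
    """Solve loads with the default vs the relocated COR, both driven by the
    subject's own kinematics."""
    if before is None:
        before = SpineLoadingModel(angles, model, activity=activity).fit(axes=axes)
    after_model = apply_cor_offset(model, offset)
    after = SpineLoadingModel(angles, after_model, activity=activity).fit(axes=axes)
    return _report_from_results(
        before, after, "reconstruction", activity,
        meta={"offset_ap_mm": offset.ap, "offset_si_mm": offset.si, "level": offset.level},
    )


def simulate_combined(
    angles: SegmentAngles,
    target: SpineRhythm,
    offset: CorOffset,
    model: SpineModel,
    activity: str | None = None,
    axes: str = "sagittal",
) -> InterventionReport:
    """Rhythm substitution and COR relocation together.  Exploratory mode:
    the interaction of the two interventions is outside the validated
    replication surface."""
    before = SpineLoadingModel(angles, model, activity=activity).fit(axes=axes)
    after_model = apply_cor_offset(model, offset)
    after_angles = substitute_rhythm(angles, target)
    after = SpineLoadingModel(after_angles, after_model, activity=activity).fit(axes=axes)
    return _report_from_results(before, after, "combined", activity)


# ---------------------------------------------------------------------------
# cohort aggregation


@dataclass
class CohortReport:
    """Pointwise mean ± SD of improvement curves and mean ΔMMA."""

    activity: str
    kind: str
    n: int
    improvement_mean: pd.DataFrame     # (101, 5)
    improvement_sd: pd.DataFrame
    mma_delta_mean: pd.Series          # (17,)

    def to_csv(self, out_dir: str | Path, stem: str = "cohort") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in (("mean", self.improvement_mean), ("sd", self.improvement_sd)):
            p = out_dir / f"{stem}_{self.kind}_improvement_{name}.csv"
            df.to_csv(p)
            paths.append(p)
        p = out_dir / f"{stem}_{self.kind}_mma_delta_mean.csv"
        self.mma_delta_mean.rename_axis("group").to_csv(p)
        paths.append(p)
        return paths


def cohort_report(reports: Sequence[InterventionReport]) -> CohortReport:
    """Aggregate subject reports sharing one activity and intervention."""
    if len(reports) == 0:
        raise AggregationError("cannot aggregate an empty collection of reports")
    activities = {r.activity for r in reports}
    kinds = {r.kind for r in reports}
    if len(activities) > 1 or len(kinds) > 1:
        raise AggregationError(
            f"mixed reports: activities={sorted(activities)}, kinds={sorted(kinds)}"
        )
    imps = np.stack([r.improvement.to_numpy() for r in reports])
    deltas = np.stack([r.mma_delta.to_numpy() for r in reports])
    ref = reports[0]
    return CohortReport(
        activity=ref.activity,
        kind=ref.kind,
        n=len(reports),
        improvement_mean=pd.DataFrame(
            imps.mean(axis=0), index=ref.improvement.index, columns=ref.improvement.columns
        ),
        improvement_sd=pd.DataFrame(
            imps.std(axis=0, ddof=0), index=ref.improvement.index,
            columns=ref.improvement.columns,
        ),
        mma_delta_mean=pd.Series(
            deltas.mean(axis=0), index=ref.mma_delta.index, name="delta_MMA_mean"
        ),
    )
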