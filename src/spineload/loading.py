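"""Model/Results interface: spine loading over one activity cycle.

:class:`SpineLoadingModel` binds a motion (segment angles, or markers plus
gait events) to a rigid-body spine model; :meth:`SpineLoadingModel.fit`
runs the quasi-static inverse-statics + min-max recruitment pipeline and
returns a :class:`SpineLoadingResults` carrying the time-normalized joint
resultant forces (body-weight units) of the five lumbar discs, the
activities of the 17 trunk muscle groups with their cycle maxima (MMA), and
solver diagnostics.  The two simulated interventions — rhythm substitution
("rehabilitation") and COR relocation ("reconstruction") — hang off the
fitted results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import NoMotionError
from .kinematics import (
    CYCLE_POINTS,
    EventTrack,
    MarkerSet,
    extract_cycle,
    time_normalize,
)
from .recruit import NetLoads, RecruitmentSolution, group_activities, net_loads, solve_cycle
from .rhythm import (
    LUMBAR_JOINTS,
    SegmentAngles,
    SpineRhythm,
    compute_rhythm,
    markers_to_segment_angles,
)
from .skeleton import CorOffset, PosedModel, SpineModel, build_default_model, pose_model


class SpineLoadingModel:
    """Spine-loading model for one subject performing one activity cycle.

    Parameters
    ----------
    angles : SegmentAngles
        Baseline-zeroed pelvis and joint angles over exactly the cycle to
        be analysed.
    skeleton : SpineModel, optional
        Mechanical system; the packaged default geometry scaled to
        ``body_mass`` when omitted.
    body_mass : float, optional
        Subject mass in kg (drives segment masses and BW normalization).
    activity : str, optional
        Label carried into results and reports (e.g. ``level_walking``).
    extra_moment : ndarray (n, 3), optional
        External moment added at every joint (e.g. stair frontal demand).
    """

    def __init__(
        self,
        angles: SegmentAngles,
        skeleton: SpineModel | None = None,
        body_mass: float | None = None,
        activity: str | None = None,
        pelvis_position: np.ndarray | None = None,
        extra_moment: np.ndarray | None = None,
    ):
        if skeleton is None:
            skeleton = build_default_model(body_mass=body_mass)
        elif body_mass is not None and abs(skeleton.body_mass - body_mass) > 1e-9:
            raise ValueError(
                "pass body_mass either via the skeleton or the model, not inconsistently"
            )
        self.angles = angles
        self.skeleton = skeleton
        self.activity = activity
        self.pelvis_position = pelvis_position
        self.extra_moment = extra_moment

    @classmethod
    def from_markers(
        cls,
        markers: MarkerSet,
        events: EventTrack | None = None,
        baseline: tuple[int, int] = (0, 1),
        leg: Literal["L", "R"] = "L",
        cycle: int = 0,
        **kwargs,
    ) -> "SpineLoadingModel":
        """Build from raw marker trajectories.

        Angles are extracted with the chord-angle convention, then (when
        ``events`` is given) restricted to one gait cycle.
        """
        angles = markers_to_segment_angles(markers, baseline=baseline)
        if events is not None:
            pelvis = extract_cycle(angles.pelvis, events, leg=leg, cycle=cycle)
            joints = extract_cycle(angles.joints, events, leg=leg, cycle=cycle)
            angles = SegmentAngles(pelvis, joints, angles.rate)
        return cls(angles, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        axes: Literal["sagittal", "3d"] = "sagittal",
        inertial: bool = False,
    ) -> "SpineLoadingResults":
        """Pose the chain, compute net loads, solve recruitment per frame,
        and time-normalize all outputs onto the 101-point cycle grid."""
        posed = pose_model(self.skeleton, self.angles, self.pelvis_position)
        net = net_loads(posed, inertial=inertial, extra_moment=self.extra_moment)
        sol = solve_cycle(posed, net, axes=axes)
        return SpineLoadingResults(self, posed, net, sol)


def fit_cycles(
    markers: MarkerSet,
    events: EventTrack,
    baseline: tuple[int, int] = (0, 1),
    leg: Literal["L", "R"] = "L",
    **kwargs,
) -> list["SpineLoadingResults"]:
    """Fit every complete cycle of a recording separately."""
    n = len(events.strikes(leg)) - 1
    if n < 1:
        raise ValueError(f"no complete cycle for leg {leg!r}")
    return [
        SpineLoadingModel.from_markers(
            markers, events, baseline=baseline, leg=leg, cycle=k, **kwargs
        ).fit()
        for k in range(n)
    ]


def average_cycles(results: list["SpineLoadingResults"]) -> dict:
    """Average normalized output curves across repeated cycles.

    Returns pointwise-mean joint-force (BW) and activity curves plus the
    MMAs of the averaged activity curves — the "average the outputs"
    convention for repeated trials of one activity.
    """
    if not results:
        raise ValueError("no results to average")
    forces = sum(r.joint_forces_bw for r in results) / len(results)
    activities = sum(r.activities for r in results) / len(results)
    return {
        "joint_forces_bw": forces,
        "activities": activities,
        "mma": activities.max(axis=0).rename("MMA"),
        "n_cycles": len(results),
    }


@dataclass
class SpineLoadingResults:
    """Fitted spine-loading outcomes for one cycle.

    All cycle curves are time-normalized to 101 points (0–100 %).  Joint
    resultant forces are full 3-D reaction magnitudes in body weights; group
    activities are the max fascicle activation within each group, with the
    MMA being the curve maximum.
    """

    model: SpineLoadingModel
    posed: PosedModel = field(repr=False)
    net: NetLoads = field(repr=False)
    solution: RecruitmentSolution = field(repr=False)

    def __post_init__(self):
        sk = self.model.skeleton
        percent = np.arange(CYCLE_POINTS, dtype=float)

        bw_all = time_normalize(self.solution.reaction_bw).values       # (101, 6)
        self.joint_forces_bw = pd.DataFrame(
            bw_all[:, :5], index=pd.Index(percent, name="percent"),
            columns=list(LUMBAR_JOINTS),
        )
        newtons = np.linalg.norm(self.solution.reactions, axis=2)
        self.joint_forces_n = pd.DataFrame(
            time_normalize(newtons).values[:, :5],
            index=pd.Index(percent, name="percent"), columns=list(LUMBAR_JOINTS),
        )
        act = group_activities(self.solution.activations, sk)
        self.activities = pd.DataFrame(
            time_normalize(act.to_numpy()).values,
            index=pd.Index(percent, name="percent"), columns=act.columns,
        )
        self.mma = self.activities.max(axis=0).rename("MMA")
        self.beta = pd.Series(
            time_normalize(self.solution.beta).values, index=percent, name="beta"
        )
        self.max_residual = float(self.solution.residuals.max())

    # -- derived quantities -------------------------------------------------

    @property
    def rhythm(self) -> SpineRhythm:
        """Rhythm of the driving kinematics (may raise
        :class:`NoMotionError` for near-static cycles)."""
        return compute_rhythm(self.model.angles)

    def peak_forces_bw(self) -> pd.Series:
        return self.joint_forces_bw.max(axis=0).rename("peak_BW")

    def mean_forces_bw(self) -> pd.Series:
        return self.joint_forces_bw.mean(axis=0).rename("mean_BW")

    # -- interventions ------------------------------------------------------

    def rehabilitate(self, target: SpineRhythm):
        """Simulated rehabilitation: re-solve with the rhythm replaced."""
        from .interventions import simulate_rehabilitation

        return simulate_rehabilitation(
            self.model.angles, target, self.model.skeleton,
            activity=self.model.activity, before=self,
        )

    def reconstruct(self, offset: CorOffset):
        """Simulated reconstruction: re-solve with the COR relocated."""
        from .interventions import simulate_reconstruction

        return simulate_reconstruction(
            self.model.angles, offset, self.model.skeleton,
            activity=self.model.activity, before=self,
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        sk = self.model.skeleton
        lines = []
        lines.append("Spine loading results")
        lines.append("=" * 60)
        lines.append(f"activity:        {self.model.activity or '<unlabelled>'}")
        lines.append(f"frames solved:   {self.posed.n_frames} "
                     f"(normalized to {CYCLE_POINTS} points)")
        lines.append(f"body mass:       {sk.body_mass:.1f} kg")
        lines.append(f"balanced axes:   {self.solution.axes}")
        lines.append(f"max residual:    {self.max_residual:.2e} Nm")
        lines.append(f"minimax beta:    peak {self.beta.max():.3f}, "
                     f"mean {self.beta.mean():.3f}")
        lines.append("")
        lines.append("joint resultant force [BW]   peak    mean")
        for j in LUMBAR_JOINTS:
            lines.append(
                f"  {j:<24}  {self.joint_forces_bw[j].max():6.3f}  "
                f"{self.joint_forces_bw[j].mean():6.3f}"
            )
        lines.append("")
        lines.append("top muscle-group MMAs")
        for g, v in self.mma.sort_values(ascending=False).head(5).items():
            lines.append(f"  {g:<24}  {v:6.3f}")
        return "\n".join(lines)

    def plot_cycle(self, ax=None):
        """Joint-force BW curves over the cycle (simple export helper)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j in LUMBAR_JOINTS:
            ax.plot(self.joint_forces_bw.index, self.joint_forces_bw[j], label=j)
        ax.set_xlabel("gait cycle [%]")
        ax.set_ylabel("joint resultant force [BW]")
        ax.legend()
        return ax
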