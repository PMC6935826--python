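"""Spine rhythm: per-joint share of the total lumbar rotation.

The spine rhythm is the fractional contribution of each intervertebral
joint (L5S1 … T12L1) to the total thorax-relative-to-pelvis sagittal
rotation, referenced to a neutral-standing baseline.  Healthy subjects and
low-back-pain patients distribute the same total trunk rotation differently
across levels, and "simulated rehabilitation" consists of replacing a
patient's rhythm with a healthy reference rhythm while leaving the total
motion untouched.

Marker-based angle extraction uses a sagittal chord-angle decomposition:
with spinous-process markers at L5, L3, L1 and thorax markers at T7/T3, the
rotation of each inter-marker chord is attributed to the joints it spans
(pelvis→L5 chord to L5S1; L5→L3 to L4L5+L3L4, split equally; L3→L1 to
L2L3+L1L2; the thorax chord closes T12L1).  Only three lumbar markers
exist, so sub-marker attribution is a declared measurement convention; the
equal split is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AggregationError,
    GeometryError,
    InvalidRhythmError,
    NoMotionError,
)
from .kinematics import MarkerSet

#: Intervertebral joints, caudal to cranial. The first five are the lumbar
#: discs on which loads are reported; T12L1 is carried internally to close
#: the pelvis→thorax chain.
JOINTS = ("L5S1", "L4L5", "L3L4", "L2L3", "L1L2", "T12L1")
LUMBAR_JOINTS = JOINTS[:5]

#: Segments of the serial chain, caudal to cranial.
SEGMENTS = ("pelvis", "L5", "L4", "L3", "L2", "L1", "thorax")

#: Default small-angle masking threshold for rhythm fractions (degrees).
MOTION_THRESHOLD_DEG = 2.0


@dataclass
class SegmentAngles:
    """Per-frame sagittal orientation of the pelvis plus the six joint angles.

    Angles are radians, zeroed at the neutral-standing baseline; flexion
    (anterior lean) is positive.  Segment absolute angles follow
    telescopically: ``segment_k = pelvis + sum(joints[:k])``.
    """

    pelvis: np.ndarray          # (n_frames,)
    joints: np.ndarray          # (n_frames, 6), ordered as JOINTS
    rate: float = 100.0

    def __post_init__(self):
        self.pelvis = np.asarray(self.pelvis, dtype=float)
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 2 or self.joints.shape[1] != len(JOINTS):
            raise ValueError(f"joints must be (n, {len(JOINTS)})")
        if self.pelvis.shape[0] != self.joints.shape[0]:
            raise ValueError("pelvis and joints frame counts differ")

    @property
    def n_frames(self) -> int:
        return self.joints.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Thorax-relative-to-pelvis angle per frame (sum of joint angles)."""
        return self.joints.sum(axis=1)

    @property
    def thorax(self) -> np.ndarray:
        return self.pelvis + self.total

    @property
    def segment_angles(self) -> np.ndarray:
        """Absolute sagittal angle of each of the 7 segments, (n, 7)."""
        cum = np.cumsum(self.joints, axis=1)
        return np.column_stack([self.pelvis, self.pelvis[:, None] + cum])

    def restrict(self, sl: np.ndarray | slice) -> "SegmentAngles":
        return SegmentAngles(self.pelvis[sl], self.joints[sl], self.rate)


@dataclass
class SpineRhythm:
    """Per-joint fractional contributions to the total lumbar rotation.

    ``fractions`` is the cycle-mean summary (length 6, sums to 1); the
    optional per-frame form and its small-angle mask are kept when the
    rhythm was computed from a motion.
    """

    fractions: np.ndarray                 # (6,)
    per_frame: np.ndarray | None = None   # (n, 6), NaN where masked
    mask: np.ndarray | None = None        # (n,), True where total motion valid

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(JOINTS),):
            raise InvalidRhythmError(f"fractions must have length {len(JOINTS)}")
        if not np.all(np.isfinite(self.fractions)):
            raise InvalidRhythmError("fractions must be finite")

    def require_valid_target(self) -> None:
        """Validate use as a substitution target: non-negative, sum ~ 1."""
        if np.any(self.fractions < 0):
            raise InvalidRhythmError("target fractions must be non-negative")
        s = self.fractions.sum()
        if abs(s - 1.0) > 1e-6:
            raise InvalidRhythmError(f"target fractions sum to {s:.6f}, expected 1")

    def normalized(self) -> "SpineRhythm":
        s = self.fractions.sum()
        if s == 0:
            raise InvalidRhythmError("cannot normalize all-zero fractions")
        return SpineRhythm(self.fractions / s)

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(JOINTS), name="fraction")


#: The "default" constant rhythm used when no subject-specific rhythm is
#: supplied (e.g. for the COR grid-search flexion task): uniform across the
#: six joints.
def uniform_rhythm() -> SpineRhythm:
    return SpineRhythm(np.full(len(JOINTS), 1.0 / len(JOINTS)))


# ---------------------------------------------------------------------------
# marker chords → angles


def _sagittal_angle(vec: np.ndarray) -> np.ndarray:
    """Angle of a 3-D vector from the lab vertical in the sagittal plane,
    positive anterior (flexion).  vec shape (..., 3)."""
    x, y = vec[..., 0], vec[..., 1]
    norm = np.hypot(x, y)
    if np.any(norm < 1e-6):
        raise GeometryError("degenerate (out-of-plane or zero) sagittal chord")
    return np.arctan2(x, y)


def markers_to_segment_angles(
    markers: MarkerSet,
    baseline: tuple[int, int] = (0, 1),
    split_lower: float = 0.5,
    split_upper: float = 0.5,
) -> SegmentAngles:
    """Extract pelvis and joint angles from the landmark set.

    Pelvis orientation comes from the LPSIS/RPSIS/IC cluster, the thorax
    from the T3–T7 chord, and the lumbar joints from the chord-angle
    attribution described in the module docstring.  All angles are zeroed
    on the mean over ``baseline`` frames (quiet standing).

    ``split_lower`` is the share of the L5→L3 chord rotation attributed to
    L4L5 (the rest goes to L3L4); ``split_upper`` likewise for L2L3 within
    the L3→L1 chord.
    """
    markers.require()
    b0, b1 = baseline
    if not 0 <= b0 < b1 <= markers.n_frames:
        raise ValueError(f"baseline range {baseline} invalid for {markers.n_frames} frames")
    if not (0.0 <= split_lower <= 1.0 and 0.0 <= split_upper <= 1.0):
        raise ValueError("split weights must lie in [0, 1]")

    P = {n: markers[n].positions for n in ("LPSIS", "RPSIS", "IC", "L5", "L3", "L1", "T7", "T3")}
    mid_psis = 0.5 * (P["LPSIS"] + P["RPSIS"])
    pel_chord = P["IC"] - mid_psis
    if np.any(np.linalg.norm(pel_chord, axis=1) < 1e-6):
        raise GeometryError("pelvis cluster degenerate: IC coincides with mid-PSIS")

    chords = {
        "pelvis": pel_chord,
        "c0": P["L5"] - P["IC"],       # spans L5S1
        "c1": P["L3"] - P["L5"],       # spans L4L5 + L3L4
        "c2": P["L1"] - P["L3"],       # spans L2L3 + L1L2
        "thorax": P["T3"] - P["T7"],   # closes T12L1
    }
    ang = {k: _sagittal_angle(v) for k, v in chords.items()}
    d = {k: a - a[b0:b1].mean() for k, a in ang.items()}

    n = markers.n_frames
    joints = np.empty((n, len(JOINTS)))
    joints[:, 0] = d["c0"] - d["pelvis"]
    lower = d["c1"] - d["c0"]
    joints[:, 1] = split_lower * lower
    joints[:, 2] = (1.0 - split_lower) * lower
    upper = d["c2"] - d["c1"]
    joints[:, 3] = split_upper * upper
    joints[:, 4] = (1.0 - split_upper) * upper
    joints[:, 5] = d["thorax"] - d["c2"]
    return SegmentAngles(d["pelvis"], joints, markers.rate)


# ---------------------------------------------------------------------------
# rhythm computation / substitution


def compute_rhythm(
    angles: SegmentAngles,
    threshold_deg: float = MOTION_THRESHOLD_DEG,
) -> SpineRhythm:
    """Per-frame and summary rhythm fractions from joint angles.

    fraction_j = joint_j / total at each frame where ``|total|`` exceeds the
    small-angle threshold; frames below it are masked (fractions are
    ill-conditioned near zero total motion).  The summary is the mean over
    unmasked frames.
    """
    total = angles.total
    mask = np.abs(total) >= np.deg2rad(threshold_deg)
    if not np.any(mask):
        raise NoMotionError(
            f"total lumbar angle never exceeds {threshold_deg} deg; rhythm undefined"
        )
    per = np.full_like(angles.joints, np.nan)
    per[mask] = angles.joints[mask] / total[mask, None]
    summary = per[mask].mean(axis=0)
    return SpineRhythm(summary, per_frame=per, mask=mask)


def substitute_rhythm(angles: SegmentAngles, target: SpineRhythm) -> SegmentAngles:
    """Redistribute each frame's total lumbar rotation by the target rhythm.

    The thorax-relative-to-pelvis angle and the pelvis trajectory are
    preserved exactly; only the split across joints changes.  This is the
    kinematic model of rehabilitation back to a reference rhythm.
    """
    target.require_valid_target()
    total = angles.total
    joints = total[:, None] * target.fractions[None, :]
    return SegmentAngles(angles.pelvis.copy(), joints, angles.rate)


def mean_rhythm(rhythms: Sequence[SpineRhythm]) -> SpineRhythm:
    """Arithmetic mean of summary fractions, renormalized to sum to 1."""
    if len(rhythms) == 0:
        raise AggregationError("cannot average an empty collection of rhythms")
    stack = np.stack([r.fractions for r in rhythms])
    return SpineRhythm(stack.mean(axis=0)).normalized()


# ---------------------------------------------------------------------------
# rhythm file I/O (summary form: joint,fraction)


def write_rhythm_csv(rhythm: SpineRhythm, path: str | Path) -> Path:
    path = Path(path)
    rhythm.to_series().rename_axis("joint").reset_index().to_csv(path, index=False)
    return path


def read_rhythm_csv(path: str | Path) -> SpineRhythm:
    df = pd.read_csv(path)
    if not {"joint", "fraction"} <= set(df.columns):
        raise InvalidRhythmError(f"{path}: expected columns joint,fraction")
    series = df.set_index("joint")["fraction"]
    try:
        fractions = series.loc[list(JOINTS)].to_numpy(dtype=float)
    except KeyError as exc:
        raise InvalidRhythmError(f"{path}: missing joint row: {exc}") from exc
    return SpineRhythm(fractions)
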