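"""Rigid-body spine model: segments, spherical joint centers, muscle fascicles.

The mechanical system is a serial chain — pelvis, five lumbar vertebrae, one
lumped thoracic segment (trunk-above-L1 + head + arms) — linked by six
spherical joints (L5S1 … T12L1) whose centers stand in for the
intervertebral discs.  Trunk muscles are straight-line tensile-only
fascicles grouped into 17 functional groups.  Joint centers can be
relocated in the sagittal plane (a center-of-rotation offset), which is the
geometric model of a disc reconstruction.

Units: metres internally, newtons, kilograms; offsets at the user surface
are millimetres.  X anterior, Y superior, Z left; flexion positive.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import GeometryError, SchemaError
from .rhythm import JOINTS, LUMBAR_JOINTS, SEGMENTS, SegmentAngles

N_GROUPS = 17


@dataclass
class Segment:
    name: str
    mass: float              # kg
    com: np.ndarray          # (3,), segment frame

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        if not self.mass > 0:
            raise SchemaError(f"segment {self.name!r}: mass must be > 0")


@dataclass
class Joint:
    name: str
    parent: str              # lower segment
    center: np.ndarray       # (3,), parent segment frame

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class MuscleFascicle:
    name: str
    group: str
    origin_segment: str
    origin_point: np.ndarray      # (3,), origin segment frame
    insertion_segment: str
    insertion_point: np.ndarray   # (3,), insertion segment frame
    strength: float               # max tensile force, N

    def __post_init__(self):
        self.origin_point = np.asarray(self.origin_point, dtype=float)
        self.insertion_point = np.asarray(self.insertion_point, dtype=float)
        if not self.strength > 0:
            raise SchemaError(f"fascicle {self.name!r}: strength must be > 0")
        if self.origin_segment == self.insertion_segment:
            raise SchemaError(
                f"fascicle {self.name!r}: origin and insertion on the same segment"
            )


@dataclass
class CorOffset:
    """Sagittal relocation of a joint center: anterior(+)/posterior(−) and
    superior(+)/inferior(−), in millimetres."""

    ap: float = 0.0
    si: float = 0.0
    level: str = "L5S1"


@dataclass
class SpineModel:
    """The assembled mechanical system (see module docstring)."""

    segments: list[Segment]                  # ordered caudal→cranial, len 7
    joints: list[Joint]                      # ordered, len 6
    fascicles: list[MuscleFascicle]
    body_mass: float                         # kg, for BW normalization
    gravity: float = 9.81                    # m/s², acts along −Y
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(s.name for s in self.segments)
        if names != SEGMENTS:
            raise SchemaError(f"segments must be {SEGMENTS} in order, got {names}")
        jnames = tuple(j.name for j in self.joints)
        if jnames != JOINTS:
            raise SchemaError(f"joints must be {JOINTS} in order, got {jnames}")
        for j, parent in zip(self.joints, SEGMENTS[:-1]):
            if j.parent != parent:
                raise SchemaError(
                    f"joint {j.name}: parent must be {parent!r}, got {j.parent!r}"
                )
        seg_index = {s: i for i, s in enumerate(SEGMENTS)}
        for f in self.fascicles:
            for seg in (f.origin_segment, f.insertion_segment):
                if seg not in seg_index:
                    raise SchemaError(f"fascicle {f.name!r} references unknown segment {seg!r}")
        groups = self.group_labels
        if len(groups) != N_GROUPS:
            raise SchemaError(f"expected {N_GROUPS} muscle groups, got {len(groups)}")
        if not self.body_mass > 0:
            raise SchemaError("body_mass must be > 0")

    # -- conveniences -------------------------------------------------------

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.fascicles:
            seen.setdefault(f.group, None)
        return tuple(seen)

    @property
    def lumbar_joints(self) -> tuple[str, ...]:
        return LUMBAR_JOINTS

    @property
    def strengths(self) -> np.ndarray:
        return np.array([f.strength for f in self.fascicles])

    def joint_index(self, level: str) -> int:
        try:
            return JOINTS.index(level)
        except ValueError:
            raise KeyError(f"unknown joint level {level!r}") from None

    def superincumbent_mass(self, level: str) -> float:
        """Total mass above a joint (segments cranial to it), kg."""
        j = self.joint_index(level)
        return sum(s.mass for s in self.segments[j + 1 :])

    def copy(self) -> "SpineModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# configuration loading


def _default_config_text() -> str:
    return resources.files("spineload.data").joinpath("default_model.yaml").read_text()


def load_model_config(path: str | Path | None = None) -> dict:
    """Load the packaged default config, or a user YAML file."""
    text = Path(path).read_text() if path is not None else _default_config_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("model config must be a mapping")
    return cfg


def build_default_model(
    config: str | Path | Mapping | None = None,
    body_mass: float | None = None,
) -> SpineModel:
    """Assemble a :class:`SpineModel` from a configuration.

    ``config`` may be a path to a YAML file, an already-parsed mapping, or
    None for the packaged default geometry.  ``body_mass`` (kg) scales the
    segment mass fractions; defaults to the config's ``default_body_mass``.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_model_config(config)
    else:
        cfg = dict(config)

    for key in ("segments", "joints", "fascicles"):
        if key not in cfg:
            raise SchemaError(f"model config missing section {key!r}")
    mass = float(body_mass if body_mass is not None else cfg.get("default_body_mass", 70.0))
    if not mass > 0:
        raise SchemaError("body_mass must be > 0")

    segments = []
    for row in cfg["segments"]:
        try:
            frac = float(row["mass_fraction"])
            if not frac > 0:
                raise SchemaError(f"segment {row.get('name')!r}: mass_fraction must be > 0")
            segments.append(Segment(row["name"], frac * mass, row["com"]))
        except KeyError as exc:
            raise SchemaError(f"segment entry missing field {exc}") from exc

    joints = []
    for row in cfg["joints"]:
        try:
            joints.append(Joint(row["name"], row["parent"], row["center"]))
        except KeyError as exc:
            raise SchemaError(f"joint entry missing field {exc}") from exc

    fascicles = []
    for row in cfg["fascicles"]:
        try:
            o_seg, *o_pt = row["origin"]
            i_seg, *i_pt = row["insertion"]
            fascicles.append(
                MuscleFascicle(
                    row["name"], row["group"],
                    o_seg, np.asarray(o_pt, dtype=float),
                    i_seg, np.asarray(i_pt, dtype=float),
                    float(row["strength"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"fascicle entry missing field {exc}") from exc

    declared = cfg.get("muscle_groups")
    model = SpineModel(
        segments, joints, fascicles,
        body_mass=mass,
        gravity=float(cfg.get("gravity", 9.81)),
        landmarks=cfg.get("landmarks", {}),
    )
    if declared is not None and set(declared) != set(model.group_labels):
        diff = set(declared) ^ set(model.group_labels)
        raise SchemaError(f"declared muscle_groups disagree with fascicle table: {sorted(diff)}")
    return model


def apply_cor_offset(model: SpineModel, offset: CorOffset) -> SpineModel:
    """Return a model whose named joint center is translated by
    (ap, si) mm in the sagittal plane of the lower segment's frame; all
    other geometry, attachments and masses are untouched."""
    j = model.joint_index(offset.level)
    out = model.copy()
    out.joints[j].center = out.joints[j].center + np.array(
        [offset.ap * 1e-3, offset.si * 1e-3, 0.0]
    )
    return out


# ---------------------------------------------------------------------------
# forward kinematics


def _sagittal_rotations(theta: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) tipping the +Y axis anteriorly by theta
    (flexion positive)."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = s
    R[..., 1, 0] = -s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


@dataclass
class PosedModel:
    """World-frame geometry of a :class:`SpineModel` over a motion.

    Arrays are indexed ``[frame, ...]``: joint centers (n, 6, 3), segment
    COMs (n, 7, 3), fascicle lower/upper attachment points (n, F, 3).
    ``crossing[i, j]`` is True when fascicle i spans joint j.
    """

    model: SpineModel
    rate: float
    joint_centers: np.ndarray
    coms: np.ndarray
    fasc_lower: np.ndarray
    fasc_upper: np.ndarray
    crossing: np.ndarray          # (F, 6) bool

    @property
    def n_frames(self) -> int:
        return self.joint_centers.shape[0]

    def segment_lengths(self) -> np.ndarray:
        """Inter-joint distances per frame, (n, 5) — rigid-body invariant."""
        d = np.diff(self.joint_centers, axis=1)
        return np.linalg.norm(d, axis=2)

    def fascicle_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.fasc_upper - self.fasc_lower, axis=2)


def pose_model(
    model: SpineModel,
    angles: SegmentAngles,
    pelvis_position: np.ndarray | None = None,
) -> PosedModel:
    """Forward kinematics of the serial chain for every frame.

    Each segment's frame originates at its inferior joint (pelvis at the
    mid-PSIS origin); segment k's world orientation is the pelvis angle plus
    the first k joint angles.
    """
    n = angles.n_frames
    phi = angles.segment_angles                     # (n, 7)
    R = _sagittal_rotations(phi)                    # (n, 7, 3, 3)
    if pelvis_position is None:
        origin0 = np.zeros((n, 3))
    else:
        origin0 = np.asarray(pelvis_position, dtype=float)
        if origin0.shape != (n, 3):
            raise ValueError("pelvis_position must be (n_frames, 3)")

    origins = np.empty((n, 7, 3))
    joint_centers = np.empty((n, 6, 3))
    origins[:, 0] = origin0
    for k, joint in enumerate(model.joints):
        jw = origins[:, k] + np.einsum("nij,j->ni", R[:, k], joint.center)
        joint_centers[:, k] = jw
        origins[:, k + 1] = jw

    coms = np.empty((n, 7, 3))
    for k, seg in enumerate(model.segments):
        coms[:, k] = origins[:, k] + np.einsum("nij,j->ni", R[:, k], seg.com)

    seg_index = {s: i for i, s in enumerate(SEGMENTS)}
    F = len(model.fascicles)
    fasc_lower = np.empty((n, F, 3))
    fasc_upper = np.empty((n, F, 3))
    crossing = np.zeros((F, 6), dtype=bool)
    for i, f in enumerate(model.fascicles):
        a, b = seg_index[f.origin_segment], seg_index[f.insertion_segment]
        pa, pb = f.origin_point, f.insertion_point
        if a > b:
            a, b, pa, pb = b, a, pb, pa
        fasc_lower[:, i] = origins[:, a] + np.einsum("nij,j->ni", R[:, a], pa)
        fasc_upper[:, i] = origins[:, b] + np.einsum("nij,j->ni", R[:, b], pb)
        crossing[i, a:b] = True

    return PosedModel(
        model, angles.rate, joint_centers, coms, fasc_lower, fasc_upper, crossing
    )


def moment_arms(posed: PosedModel, joint: str) -> np.ndarray:
    """Per-fascicle 3-D moment-arm vectors about one joint, (n, F, 3).

    For a fascicle crossing the joint, the moment of a unit tensile force on
    the superincumbent body about the joint center is
    ``(upper_attachment − center) × u`` with ``u`` the unit vector from the
    upper toward the lower attachment (the direction the muscle pulls the
    upper part).  Fascicles not crossing the joint contribute zero.
    """
    j = posed.model.joint_index(joint)
    c = posed.joint_centers[:, j]                       # (n, 3)
    d = posed.fasc_lower - posed.fasc_upper             # (n, F, 3), upper→lower
    L = np.linalg.norm(d, axis=2)
    cross_mask = posed.crossing[:, j]
    if np.any(L[:, cross_mask] < 1e-9):
        bad = [
            posed.model.fascicles[i].name
            for i in np.where(cross_mask)[0]
            if np.any(L[:, i] < 1e-9)
        ]
        raise GeometryError(f"zero-length posed fascicle(s): {bad}")
    u = np.zeros_like(d)
    ok = L > 1e-9
    u[ok] = d[ok] / L[ok][:, None]
    lever = posed.fasc_upper - c[:, None, :]
    arms = np.cross(lever, u)
    arms[:, ~cross_mask, :] = 0.0
    return arms
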