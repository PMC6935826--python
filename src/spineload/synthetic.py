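"""Synthetic kinematics: marker trajectories and segment angles for level
walking, stair climbing and trunk flexion, with healthy and LDH rhythm
profiles.

The generator is the package's study-condition definition: it emulates the
recording protocol (8-landmark spinal/pelvic marker set at 100 Hz, a ≥5 s
neutral-standing baseline, three repeated gait cycles with heel-strike
annotations) without reproducing any recorded subject.  A subject's total
thorax-on-pelvis sagittal rotation follows a low-order harmonic waveform
per activity; per-joint angles are the total distributed by the subject's
spine rhythm (plus optional seeded per-frame jitter); markers are placed by
forward kinematics of the chord chain used by the inverse extraction, so
noise-free kinematics are exactly recoverable.

Randomness discipline: a single integer seed feeds ``numpy``'s PCG64
``default_rng``; cohort generation draws one child seed (< 2**31) per
subject from the root stream, and each subject owns an independent
generator, so cohorts are reproducible subject-by-subject.

Default group rhythms are invented (the condition they emulate is that LDH
patients load the lower lumbar levels with a larger share of the total
rotation than healthy controls); cohort mass/height distributions follow
published adult-male cohort statistics (63.5±8.4 kg healthy, 67.4±5.3 kg
LDH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SchemaError
from .kinematics import EventTrack, MarkerSet, MarkerTrajectory
from .rhythm import JOINTS, SegmentAngles, SpineRhythm, uniform_rhythm
from .skeleton import _sagittal_rotations, load_model_config

#: Default group-mean rhythms (L5S1, L4L5, L3L4, L2L3, L1L2, T12L1).
HEALTHY_RHYTHM = (0.28, 0.24, 0.18, 0.13, 0.10, 0.07)
LDH_RHYTHM = (0.38, 0.30, 0.14, 0.09, 0.06, 0.03)


@dataclass
class SubjectProfile:
    """One synthetic subject's generating parameters."""

    subject_id: str
    group: str                      # "healthy" | "ldh"
    mass: float                     # kg
    height: float                   # m
    rhythm: np.ndarray              # (6,), sums to 1
    rhythm_jitter_sd: float = 0.0   # per-frame fraction jitter SD
    marker_noise_sd: float = 0.0    # mm
    seed: int = 0

    def __post_init__(self):
        self.rhythm = np.asarray(self.rhythm, dtype=float)
        if self.rhythm.shape != (len(JOINTS),):
            raise SchemaError("rhythm must have 6 fractions")
        if np.any(self.rhythm < 0) or abs(self.rhythm.sum() - 1.0) > 1e-9:
            raise SchemaError("rhythm fractions must be >= 0 and sum to 1")
        if self.rhythm_jitter_sd < 0 or self.marker_noise_sd < 0:
            raise SchemaError("jitter/noise SDs must be >= 0")
        if self.group not in ("healthy", "ldh"):
            raise SchemaError(f"unknown group {self.group!r}")


@dataclass
class ActivityTemplate:
    """Waveform recipe for one activity.

    The total lumbar angle over a cycle is
    ``offset + sum_k amp_k * sin(2 pi k t/T + phase_k)`` (degrees); the
    pelvis oscillates with a small first-harmonic term.
    ``frontal_moment_amp`` adds a first-harmonic frontal-plane external
    moment (Nm) — the stair-climbing asymmetry term that exercises
    left/right muscle pairs under 3-D balance.
    """

    name: str
    cycle_duration: float                 # s
    total_offset_deg: float
    harmonics: tuple[tuple[float, float], ...]   # (amplitude deg, phase rad)
    pelvis_amp_deg: float = 2.0
    frontal_moment_amp: float = 0.0       # Nm
    n_cycles: int = 3
    baseline_duration: float = 5.0        # s of quiet standing
    rate: float = 100.0                   # Hz

    def __post_init__(self):
        if self.rate <= 0 or self.cycle_duration <= 0:
            raise SchemaError("rate and cycle_duration must be > 0")


def level_walking() -> ActivityTemplate:
    return ActivityTemplate(
        name="level_walking", cycle_duration=1.1,
        total_offset_deg=8.0, harmonics=((4.0, 0.0), (1.5, 0.7)),
        pelvis_amp_deg=2.0,
    )


def stair_climbing() -> ActivityTemplate:
    return ActivityTemplate(
        name="stair_climbing", cycle_duration=1.4,
        total_offset_deg=15.0, harmonics=((8.0, 0.0), (3.0, 1.1)),
        pelvis_amp_deg=3.0, frontal_moment_amp=5.0,
    )


TEMPLATES = {"level_walking": level_walking, "stair_climbing": stair_climbing}


@dataclass
class SyntheticSubject:
    """Generated data plus the ground truth used to make it."""

    profile: SubjectProfile
    template: ActivityTemplate
    markers: MarkerSet
    events: EventTrack
    angles: SegmentAngles           # ground-truth, full recording
    baseline: tuple[int, int]       # frame range of quiet standing
    frontal_moment: np.ndarray      # (n_frames,) Nm about +X


def _total_waveform(template: ActivityTemplate, t_cycle: np.ndarray) -> np.ndarray:
    total = np.full_like(t_cycle, template.total_offset_deg)
    for k, (amp, phase) in enumerate(template.harmonics, start=1):
        total += amp * np.sin(2 * np.pi * k * t_cycle / template.cycle_duration + phase)
    return total


def generate_subject(
    profile: SubjectProfile, template: ActivityTemplate
) -> SyntheticSubject:
    """Generate one subject's recording for one activity.

    Returns markers (mm, with Gaussian noise of ``profile.marker_noise_sd``),
    heel-strike events at cycle boundaries, and the noise-free ground-truth
    segment angles.
    """
    rng = np.random.default_rng(profile.seed)
    rate = template.rate
    nb = int(round(template.baseline_duration * rate))
    nc = int(round(template.cycle_duration * rate))
    n = nb + template.n_cycles * nc + 1

    total_deg = np.zeros(n)
    pelvis_deg = np.zeros(n)
    frontal = np.zeros(n)
    t_move = (np.arange(n - nb)) / rate
    total_deg[nb:] = _total_waveform(template, t_move)
    pelvis_deg[nb:] = template.pelvis_amp_deg * np.sin(
        2 * np.pi * t_move / template.cycle_duration
    )
    frontal[nb:] = template.frontal_moment_amp * np.sin(
        2 * np.pi * t_move / template.cycle_duration
    )

    fractions = np.tile(profile.rhythm, (n, 1))
    if profile.rhythm_jitter_sd > 0:
        jit = rng.normal(0.0, profile.rhythm_jitter_sd, size=(n, len(JOINTS)))
        fractions = np.clip(fractions + jit, 1e-4, None)
        fractions /= fractions.sum(axis=1, keepdims=True)

    total = np.deg2rad(total_deg)
    pelvis = np.deg2rad(pelvis_deg)
    joints = total[:, None] * fractions
    angles = SegmentAngles(pelvis, joints, rate)

    markers = _markers_from_angles(angles, noise_sd_mm=profile.marker_noise_sd, rng=rng)
    events = EventTrack(
        sorted(
            [("heel_strike_L", nb + k * nc) for k in range(template.n_cycles + 1)]
            + [("heel_strike_R", nb + k * nc + nc // 2) for k in range(template.n_cycles)],
            key=lambda e: e[1],
        )
    )
    return SyntheticSubject(
        profile, template, markers, events, angles, (0, nb or 1), frontal
    )


def _markers_from_angles(
    angles: SegmentAngles,
    noise_sd_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    config: dict | None = None,
) -> MarkerSet:
    """Forward kinematics of the marker chain (module docstring); output mm."""
    cfg = config or load_model_config()
    lm = cfg["landmarks"]
    pel = {k: np.asarray(v, dtype=float) for k, v in lm["pelvis"].items()}
    chain = {k: np.asarray(v, dtype=float) for k, v in lm["chain"].items()}

    th = angles.joints
    a0 = angles.pelvis + th[:, 0]
    a1 = a0 + th[:, 1] + th[:, 2]
    a2 = a1 + th[:, 3] + th[:, 4]
    a_th = a2 + th[:, 5]

    Rp = _sagittal_rotations(angles.pelvis)
    pos = {k: np.einsum("nij,j->ni", Rp, v) for k, v in pel.items()}
    pos["L5"] = pos["IC"] + np.einsum(
        "nij,j->ni", _sagittal_rotations(a0), chain["L5_from_IC"]
    )
    pos["L3"] = pos["L5"] + np.einsum(
        "nij,j->ni", _sagittal_rotations(a1), chain["L3_from_L5"]
    )
    pos["L1"] = pos["L3"] + np.einsum(
        "nij,j->ni", _sagittal_rotations(a2), chain["L1_from_L3"]
    )
    Rt = _sagittal_rotations(a_th)
    pos["T7"] = pos["L1"] + np.einsum("nij,j->ni", Rt, chain["T7_from_L1"])
    pos["T3"] = pos["T7"] + np.einsum("nij,j->ni", Rt, chain["T3_from_T7"])

    trajs = {}
    for name, p in pos.items():
        mm = p * 1000.0
        if noise_sd_mm > 0:
            if rng is None:
                rng = np.random.default_rng()
            mm = mm + rng.normal(0.0, noise_sd_mm, size=mm.shape)
        trajs[name] = MarkerTrajectory(name, mm, angles.rate)
    return MarkerSet(trajs, angles.rate)


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    n_healthy: int = 26,
    n_ldh: int = 7,
    seed: int = 0,
    rhythm_profile_sd: float = 0.02,
    rhythm_jitter_sd: float = 0.0,
    marker_noise_sd: float = 0.0,
) -> list[SubjectProfile]:
    """Draw subject profiles for a healthy + LDH cohort.

    Per-subject rhythms are the group mean plus Gaussian jitter
    (``rhythm_profile_sd``), clipped non-negative and renormalized; masses
    and heights are drawn from the group distributions noted in the module
    docstring.  Each profile carries its own child seed.
    """
    if n_healthy < 0 or n_ldh < 0:
        raise SchemaError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    profiles = []
    specs = [("healthy", n_healthy, HEALTHY_RHYTHM, 63.5, 8.4, 1.699, 0.059),
             ("ldh", n_ldh, LDH_RHYTHM, 67.4, 5.3, 1.701, 0.034)]
    for group, count, mean_rhythm, m_mu, m_sd, h_mu, h_sd in specs:
        for i in range(count):
            child_seed = int(rng.integers(2**31))
            fr = np.asarray(mean_rhythm) + rng.normal(0, rhythm_profile_sd, len(JOINTS))
            fr = np.clip(fr, 1e-3, None)
            fr /= fr.sum()
            mass = float(np.clip(rng.normal(m_mu, m_sd), 40.0, 120.0))
            height = float(np.clip(rng.normal(h_mu, h_sd), 1.4, 2.1))
            profiles.append(
                SubjectProfile(
                    subject_id=f"{group}_{i:02d}", group=group,
                    mass=mass, height=height, rhythm=fr,
                    rhythm_jitter_sd=rhythm_jitter_sd,
                    marker_noise_sd=marker_noise_sd, seed=child_seed,
                )
            )
    return profiles


def generate_flexion_task(
    amplitude_deg: float = 45.0,
    rhythm: SpineRhythm | None = None,
    n_frames: int = 51,
    rate: float = 100.0,
) -> SegmentAngles:
    """Smooth 0→amplitude trunk-flexion ramp distributed by a rhythm.

    The ramp is a cubic smoothstep; the pelvis stays neutral.  This is the
    driving motion of the COR grid search (run under the default uniform
    rhythm unless another is given).
    """
    if amplitude_deg <= 0:
        raise ValueError("flexion amplitude must be > 0 degrees")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rhythm = rhythm or uniform_rhythm()
    rhythm.require_valid_target()
    s = np.linspace(0.0, 1.0, n_frames)
    ramp = np.deg2rad(amplitude_deg) * (3 * s**2 - 2 * s**3)
    joints = ramp[:, None] * rhythm.fractions[None, :]
    return SegmentAngles(np.zeros(n_frames), joints, rate)
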