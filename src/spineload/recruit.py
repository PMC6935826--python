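"""Net intervertebral loads and min-max muscle recruitment.

Quasi-static inverse statics gives, for each joint, the gravitational (and
optionally inertial) force and moment of the superincumbent body that the
muscles and the joint must balance.  Muscle forces are then distributed by
the minimum-maximum criterion: minimize the largest muscle activation
``a_i = f_i / N_i`` subject to moment equilibrium and tensile-only forces,

    minimize beta  s.t.  sum_i r_ij f_i = -M_j,   0 <= f_i <= beta N_i,

resolved lexicographically (saturate-and-resolve) because the plain
min-max optimum generally leaves the sub-maximal forces non-unique.  Joint
reactions follow by force balance of the superincumbent body and are
reported both in newtons and normalized to body weight (BW).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import InfeasibleError
from .rhythm import JOINTS
from .skeleton import PosedModel, SpineModel, moment_arms

logger = logging.getLogger(__name__)

#: relative moment-equilibrium residual gate for a solved frame
RESIDUAL_RTOL = 1e-6
#: activation margin for saturation detection in the lexicographic loop
SATURATION_TOL = 1e-7

_AXES = {"sagittal": (2,), "3d": (2, 0)}   # z = flexion/extension, x = lateral


@dataclass
class NetLoads:
    """Per-frame, per-joint external force and moment of the superincumbent
    body (gravity plus optional inertial terms), (n, 6, 3) each, N / Nm."""

    forces: np.ndarray
    moments: np.ndarray


def net_loads(
    posed: PosedModel,
    inertial: bool = False,
    extra_moment: np.ndarray | None = None,
) -> NetLoads:
    """Top-down inverse statics.

    For joint j the superincumbent segments are those cranial to it; their
    weight ``m g`` (acting along −Y) and its moment about the joint center
    are summed.  With ``inertial=True``, COM accelerations from central
    differences add d'Alembert terms ``−m a`` (point-mass segments; no
    angular inertia).  ``extra_moment`` (n, 3) is added to every joint's
    moment — a simple handle for task asymmetries such as the frontal-plane
    demand of stair climbing.
    """
    model = posed.model
    n = posed.n_frames
    g = np.array([0.0, -model.gravity, 0.0])
    masses = np.array([s.mass for s in model.segments])

    acc = np.zeros_like(posed.coms)
    if inertial and n >= 3:
        dt = 1.0 / posed.rate
        acc[1:-1] = (posed.coms[2:] - 2 * posed.coms[1:-1] + posed.coms[:-2]) / dt**2
        acc[0], acc[-1] = acc[1], acc[-2]

    forces = np.zeros((n, 6, 3))
    moments = np.zeros((n, 6, 3))
    for j in range(6):
        above = slice(j + 1, 7)
        m_above = masses[above]
        seg_force = m_above[None, :, None] * (g[None, None, :] - acc[:, above])
        forces[:, j] = seg_force.sum(axis=1)
        lever = posed.coms[:, above] - posed.joint_centers[:, j : j + 1]
        moments[:, j] = np.cross(lever, seg_force).sum(axis=1)
    if extra_moment is not None:
        extra = np.asarray(extra_moment, dtype=float)
        if extra.shape != (n, 3):
            raise ValueError("extra_moment must be (n_frames, 3)")
        moments += extra[:, None, :]
    return NetLoads(forces, moments)


# ---------------------------------------------------------------------------
# min-max LP, lexicographic


def solve_minmax_frame(
    A: np.ndarray,
    b: np.ndarray,
    strengths: np.ndarray,
    labels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, float]:
    """Lexicographic min-max recruitment for one equilibrium system.

    ``A`` (m, F) maps fascicle forces onto the balanced moment components,
    ``b`` (m,) is the demand, ``strengths`` (F,) the tensile capacities.
    Returns ``(forces, beta)`` with ``beta`` the minimax activation level.

    The loop solves the min-β LP, freezes fascicles saturated at β·N, moves
    them to the right-hand side, and re-minimizes the maximum over the
    remainder until no activation is left (or every fascicle is frozen).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    m, nf = A.shape
    labels = labels or tuple(f"eq{j}" for j in range(m))

    f = np.zeros(nf)
    fixed = np.zeros(nf, dtype=bool)
    beta_star: float | None = None
    for _ in range(nf + 1):
        free = ~fixed
        k = int(free.sum())
        if k == 0:
            break
        Af = A[:, free]
        bf = b - A[:, fixed] @ f[fixed]
        Nf = strengths[free]
        c = np.r_[np.zeros(k), 1.0]
        A_eq = np.hstack([Af, np.zeros((m, 1))])
        A_ub = np.hstack([np.eye(k), -Nf[:, None]])
        res = linprog(
            c, A_ub=A_ub, b_ub=np.zeros(k), A_eq=A_eq, b_eq=bf,
            bounds=[(0.0, None)] * (k + 1), method="highs",
        )
        if not res.success:
            dead = [
                labels[j]
                for j in range(m)
                if np.all(np.abs(A[j]) < 1e-12) and abs(b[j]) > 1e-9
            ]
            which = dead or list(labels)
            raise InfeasibleError(
                f"recruitment infeasible (no tensile solution) at {which}",
                joints=tuple(which),
            )
        beta = float(res.x[-1])
        f[free] = res.x[:k]
        if beta_star is None:
            beta_star = beta
        if beta <= 1e-9:
            break
        sat_local = res.x[:k] >= (beta - SATURATION_TOL) * Nf
        if not np.any(sat_local):
            break
        # freeze at the LP's own values (== beta*N within LP tolerance);
        # substituting exact beta*N would leak the LP tolerance into the
        # equality residual
        fixed[np.where(free)[0][sat_local]] = True

    np.clip(f, 0.0, None, out=f)       # scrub LP round-off below zero
    resid = np.max(np.abs(A @ f - b)) if m else 0.0
    gate = RESIDUAL_RTOL * (1.0 + (np.max(np.abs(b)) if m else 0.0))
    if resid > gate:
        raise InfeasibleError(
            f"equilibrium residual {resid:.2e} exceeds gate {gate:.2e}",
            joints=labels,
        )
    return f, float(beta_star if beta_star is not None else 0.0)


@dataclass
class RecruitmentSolution:
    """Cycle-wise recruitment output.

    forces/activations (n, F); beta (n,); residuals (n,); reactions
    (n, 6, 3) N; reaction_bw (n, 6) — full 3-D reaction magnitude over body
    weight (the compressive-projection column is available from
    ``reactions`` and the posed geometry).
    """

    forces: np.ndarray
    activations: np.ndarray
    beta: np.ndarray
    residuals: np.ndarray
    reactions: np.ndarray
    reaction_bw: np.ndarray
    axes: str


def _equilibrium_system(posed: PosedModel, axes: str):
    comp = _AXES[axes]
    arms = np.stack([moment_arms(posed, j) for j in JOINTS], axis=1)  # (n,6,F,3)
    rows = []
    labels = []
    for j, joint in enumerate(JOINTS):
        for c in comp:
            rows.append(arms[:, j, :, c])
            labels.append(f"{joint}:{'xyz'[c]}")
    return np.stack(rows, axis=1), tuple(labels)      # (n, m, F)


def solve_cycle(
    posed: PosedModel,
    net: NetLoads,
    axes: str = "sagittal",
) -> RecruitmentSolution:
    """Solve min-max recruitment at every frame and assemble reactions.

    ``axes='sagittal'`` balances the flexion/extension moment at the six
    joints; ``'3d'`` adds the frontal (lateral-bend) axis.  Axial twist is
    never balanced: the near-vertical fascicle set has negligible twist
    capacity and the driving kinematics carry no twist demand.
    """
    if axes not in _AXES:
        raise ValueError(f"axes must be one of {sorted(_AXES)}")
    model = posed.model
    n = posed.n_frames
    strengths = model.strengths
    Asys, labels = _equilibrium_system(posed, axes)
    comp = _AXES[axes]
    demand = np.concatenate(
        [-net.moments[:, j, list(comp)] for j in range(6)], axis=1
    )  # (n, m) ordered joint-major like Asys

    F = len(model.fascicles)
    forces = np.zeros((n, F))
    beta = np.zeros(n)
    for i in range(n):
        forces[i], beta[i] = solve_minmax_frame(Asys[i], demand[i], strengths, labels)
    residuals = np.max(np.abs(np.einsum("nmf,nf->nm", Asys, forces) - demand), axis=1)

    activations = forces / strengths[None, :]
    if np.any(activations > 1.0 + 1e-9):
        logger.warning(
            "muscle overload: max activation %.3f exceeds 1 (demand beyond strength)",
            float(activations.max()),
        )

    reactions = joint_reactions(forces, net, posed)
    bw = model.body_mass * model.gravity
    reaction_bw = np.linalg.norm(reactions, axis=2) / bw
    return RecruitmentSolution(
        forces, activations, beta, residuals, reactions, reaction_bw, axes
    )


def joint_reactions(
    forces: np.ndarray, net: NetLoads, posed: PosedModel
) -> np.ndarray:
    """Joint reaction force vectors (n, 6, 3).

    Force balance of the superincumbent body at joint j: external load +
    muscle pulls (each crossing fascicle pulls its upper attachment toward
    the lower one) + reaction = 0.
    """
    d = posed.fasc_lower - posed.fasc_upper            # upper→lower pull direction
    L = np.linalg.norm(d, axis=2)
    u = np.zeros_like(d)
    ok = L > 1e-9
    u[ok] = d[ok] / L[ok][:, None]
    pulls = forces[:, :, None] * u                     # (n, F, 3)
    reactions = np.empty((posed.n_frames, 6, 3))
    for j in range(6):
        muscle = pulls[:, posed.crossing[:, j]].sum(axis=1)
        reactions[:, j] = -(net.forces[:, j] + muscle)
    return reactions


def group_activities(
    activations: np.ndarray, model: SpineModel
) -> pd.DataFrame:
    """Per-frame group activity: the max activation among each group's
    fascicles; columns ordered by the model's 17 group labels."""
    groups = model.group_labels
    cols = {}
    for g in groups:
        members = [i for i, f in enumerate(model.fascicles) if f.group == g]
        cols[g] = activations[:, members].max(axis=1)
    return pd.DataFrame(cols, columns=list(groups))
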