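"""Brute-force lexicographic min-max oracle for tiny recruitment systems.

Fully independent of the LP implementation: everything is derived from the
support function of the achievable-moment zonotope
``Z(c) = {sum_i a_i N_i A_i : 0 <= a_i <= c_i}``, whose membership test is

    b in Z(c)  iff  u.b <= h_c(u) = sum_i c_i max(0, u.(N_i A_i))  for all u.

* the minimax level is the zonotope gauge ``beta* = max_u (u.b)/h_1(u)``
  (closed form over u = ±1 for one balanced joint; a dense direction grid
  with contracting refinement for two);
* the lexicographic solution follows the classical recursion: find the
  level, mark the fascicles whose individual cap cannot be reduced below
  the level without losing feasibility (again a direction search), freeze
  them there, move their moments to the right-hand side, repeat.

Intended for systems with <= 4 fascicles and 1–2 balanced joints.
"""

from __future__ import annotations

import numpy as np

_N_DIRS = 8192
_REFINE_ITERS = 60
_REFINE_SHRINK = 0.35


def _directions(m: int) -> np.ndarray:
    if m == 1:
        return np.array([[1.0], [-1.0]])
    theta = np.linspace(0.0, 2 * np.pi, _N_DIRS, endpoint=False)
    return np.stack([np.cos(theta), np.sin(theta)], axis=1)


def _refine_max(fn, theta0: float) -> float:
    """Contracting 1-D refinement of max fn(theta) around theta0."""
    c, half = theta0, 2 * np.pi / _N_DIRS
    best = -np.inf
    for _ in range(_REFINE_ITERS):
        t = np.linspace(c - half, c + half, 33)
        v = fn(t)
        i = int(np.argmax(v))
        best = max(best, float(v[i]))
        c = t[i]
        half *= _REFINE_SHRINK
    return best


def _max_over_directions(fn_theta, fn_u, m: int) -> float:
    """Maximize a directional function: exact over ±1 for m=1, dense grid
    plus refinement for m=2."""
    if m == 1:
        return float(np.max(fn_u(_directions(1))))
    theta = np.linspace(0.0, 2 * np.pi, _N_DIRS, endpoint=False)
    v = fn_theta(theta)
    i = int(np.argmax(v))
    return max(float(v[i]), _refine_max(fn_theta, theta[i]))


def minimax_level(
    AN: np.ndarray, b: np.ndarray, active: np.ndarray, scale: float = 1.0
) -> float:
    """Smallest uniform activation cap beta on the active columns such that
    b is achievable; +inf when no cap suffices.  ``scale`` sets the noise
    floor below which a positive u.b is treated as round-off."""
    m = AN.shape[0]
    cols = AN[:, active]
    if not np.any(np.abs(b) > 1e-9 * scale):
        return 0.0

    def ratio_u(U: np.ndarray) -> np.ndarray:
        ub = U @ b
        h = np.clip(U @ cols, 0.0, None).sum(axis=1)
        out = np.full(U.shape[0], -np.inf)
        pos = ub > 1e-7 * scale
        out[pos & (h > 1e-14)] = (ub / np.maximum(h, 1e-300))[pos & (h > 1e-14)]
        out[pos & (h <= 1e-14)] = np.inf
        return out

    def ratio_theta(theta: np.ndarray) -> np.ndarray:
        return ratio_u(np.stack([np.cos(theta), np.sin(theta)], axis=1))

    out = _max_over_directions(ratio_theta, ratio_u, m)
    # -inf: no direction demands a positive moment beyond the noise floor,
    # so the residual is achievable with zero activation
    return 0.0 if out == -np.inf else out


def _infeasibility(AN: np.ndarray, b: np.ndarray, caps: np.ndarray) -> float:
    """max_u (u.b − h_caps(u)); > 0 means b is outside the capped zonotope."""
    m = AN.shape[0]

    def margin_u(U: np.ndarray) -> np.ndarray:
        return U @ b - (np.clip(U @ AN, 0.0, None) * caps[None, :]).sum(axis=1)

    def margin_theta(theta: np.ndarray) -> np.ndarray:
        return margin_u(np.stack([np.cos(theta), np.sin(theta)], axis=1))

    return _max_over_directions(margin_theta, margin_u, m)


def brute_force_minimax(
    A: np.ndarray,
    b: np.ndarray,
    strengths: np.ndarray,
    level_tol: float = 1e-8,
    forced_rel: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Lexicographic min-max solution (forces, minimax beta)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).copy()
    N = np.asarray(strengths, dtype=float)
    n = A.shape[1]
    AN = A * N[None, :]

    a = np.zeros(n)
    active = np.ones(n, dtype=bool)
    beta_star: float | None = None
    scale = 1.0 + np.abs(b).max(initial=0.0)

    for _ in range(n):
        if not active.any():
            break
        b_res = b - AN[:, ~active] @ a[~active]
        beta = minimax_level(AN, b_res, active, scale=scale)
        if not np.isfinite(beta):
            raise ValueError("oracle: system infeasible under tensile-only forces")
        if beta_star is None:
            beta_star = beta
        if beta <= level_tol:
            break
        forced = []
        idx = np.where(active)[0]
        for i in idx:
            caps = np.zeros(n)
            caps[active] = beta
            caps[i] = beta * (1.0 - forced_rel)
            gap = _infeasibility(AN[:, active], b_res, caps[active])
            # a genuinely compensable reduction leaves the gap at numerical
            # zero; a forced one opens a gap of order forced_rel * beta
            if gap > 1e-10 * scale:
                forced.append(i)
        if not forced:
            raise ValueError("oracle: no fascicle forced at the level (degenerate tie)")
        for i in forced:
            a[i] = beta
            active[i] = False

    resid = np.abs(AN @ a - b).max(initial=0.0)
    if resid > 1e-6 * scale:
        raise ValueError(f"oracle: residual {resid:.2e} too large")
    return a * N, float(beta_star if beta_star is not None else 0.0)


def random_toy_system(
    rng: np.random.Generator,
    n_fascicles: int | None = None,
    n_joints: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A random feasible toy system (A, b, strengths).

    Moment arms avoid near-zero magnitudes; the demand is constructed from
    a random feasible activation vector, so a tensile solution exists.
    """
    nf = int(n_fascicles if n_fascicles is not None else rng.integers(2, 5))
    nj = int(n_joints if n_joints is not None else rng.integers(1, 3))
    nj = min(nj, nf - 1) if nf > 1 else 1
    signs = rng.choice([-1.0, 1.0], size=(nj, nf))
    A = signs * rng.uniform(0.02, 0.08, size=(nj, nf))
    N = rng.uniform(200.0, 1500.0, size=nf)
    a_gen = rng.uniform(0.0, 0.8, size=nf)
    b = (A * N[None, :]) @ a_gen
    return A, b, N
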