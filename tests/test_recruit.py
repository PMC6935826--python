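"""Inverse statics, min-max recruitment and joint reactions."""

import numpy as np
import pytest

import spineload as sl
from spineload.recruit import (
    group_activities,
    joint_reactions,
    net_loads,
    solve_cycle,
    solve_minmax_frame,
)
from spineload.skeleton import pose_model

from _minimax_oracle import brute_force_minimax, random_toy_system
from conftest import make_custom_model


def neutral(n=1):
    return sl.SegmentAngles(np.zeros(n), np.zeros((n, 6)))


def lever_model(thorax_x=0.10, body_mass=70.0, thorax_mass=40.0, fascicles=None):
    """Toy chain: one heavy thorax COM at ``thorax_x`` anterior, near-massless
    lumbar vertebrae, joints stacked vertically."""
    return make_custom_model(
        fascicles or [],
        thorax_mass_fraction=thorax_mass / body_mass,
        thorax_com=(thorax_x, 0.0, 0.0),   # thorax COM at the T12L1 center
        body_mass=body_mass,
    )


class TestNetLoads:
    def test_coms_above_centers_give_zero_sagittal_moment(self):
        model = lever_model(thorax_x=0.0)
        net = net_loads(pose_model(model, neutral()))
        np.testing.assert_allclose(net.moments[0, :, 2], 0.0, atol=1e-6)

    def test_single_lever_arithmetic(self):
        """40 kg thorax 0.10 m anterior of every joint center: sagittal
        gravity moment magnitude is 40 * 9.81 * 0.10 = 39.24 Nm."""
        model = lever_model(thorax_x=0.10, thorax_mass=40.0)
        net = net_loads(pose_model(model, neutral()))
        assert abs(net.moments[0, 0, 2]) == pytest.approx(39.24, abs=1e-6)
        # anterior COM demands extension: gravity moment is flexion (−z)
        assert net.moments[0, 0, 2] < 0

    def test_gravity_force_magnitude_pose_invariant(self, default_model):
        rng = np.random.default_rng(2)
        ang = sl.SegmentAngles(rng.normal(0, 0.3, 5), rng.normal(0, 0.2, (5, 6)))
        net = net_loads(pose_model(default_model, ang))
        for j, joint in enumerate(sl.JOINTS):
            expect = default_model.superincumbent_mass(joint) * default_model.gravity
            np.testing.assert_allclose(
                np.linalg.norm(net.forces[:, j], axis=1), expect, rtol=1e-12
            )

    def test_extra_moment_added_at_every_joint(self, default_model):
        posed = pose_model(default_model, neutral(3))
        extra = np.tile([0.0, 0.0, 2.5], (3, 1))
        base = net_loads(posed)
        plus = net_loads(posed, extra_moment=extra)
        np.testing.assert_allclose(plus.moments - base.moments, 2.5 * np.tile(
            [0, 0, 1.0], (3, 6, 1)), atol=1e-12)


class TestMinMaxFrame:
    def test_zero_demand_zero_forces(self):
        f, beta = solve_minmax_frame(
            np.array([[0.05, -0.03]]), np.array([0.0]), np.array([500.0, 500.0])
        )
        np.testing.assert_allclose(f, 0.0, atol=1e-9)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_single_extensor_closed_form(self):
        """a = M / (r N): 25 Nm over a 0.05 m arm and 1000 N strength."""
        f, beta = solve_minmax_frame(
            np.array([[0.05]]), np.array([25.0]), np.array([1000.0])
        )
        assert f[0] == pytest.approx(500.0, abs=1e-3)
        assert beta == pytest.approx(0.5, abs=1e-6)

    def test_two_synergists_share_by_strength(self):
        """a = M / (r (N1+N2)) for equal arms; forces split as a*N_i."""
        f, beta = solve_minmax_frame(
            np.array([[0.05, 0.05]]), np.array([30.0]), np.array([1000.0, 500.0])
        )
        assert beta == pytest.approx(0.4, abs=1e-6)
        np.testing.assert_allclose(f, [400.0, 200.0], atol=1e-3)

    def test_overload_is_allowed_not_an_error(self):
        f, beta = solve_minmax_frame(
            np.array([[0.05]]), np.array([100.0]), np.array([1000.0])
        )
        assert beta == pytest.approx(2.0, abs=1e-6)
        assert f[0] == pytest.approx(2000.0, abs=1e-3)

    def test_unreachable_demand_is_infeasible(self):
        with pytest.raises(sl.InfeasibleError):
            solve_minmax_frame(
                np.array([[0.0]]), np.array([5.0]), np.array([1000.0]),
                labels=("L5S1:z",),
            )

    def test_inactive_fascicle_removal_preserves_solution(self):
        """Dropping a fascicle that carried no force leaves everything
        unchanged (conservation of the lexicographic solution)."""
        A = np.array([[0.05, 0.04, -0.03]])
        N = np.array([1000.0, 800.0, 600.0])
        f3, b3 = solve_minmax_frame(A, np.array([40.0]), N)
        assert f3[2] == pytest.approx(0.0, abs=1e-9)   # antagonist stays off
        f2, b2 = solve_minmax_frame(A[:, :2], np.array([40.0]), N[:2])
        assert b2 == pytest.approx(b3, abs=1e-9)
        np.testing.assert_allclose(f2, f3[:2], atol=1e-6)

    def test_strength_doubling_halves_activation_not_force(self):
        f1, b1 = solve_minmax_frame(
            np.array([[0.05]]), np.array([25.0]), np.array([1000.0])
        )
        f2, b2 = solve_minmax_frame(
            np.array([[0.05]]), np.array([25.0]), np.array([2000.0])
        )
        assert b2 == pytest.approx(b1 / 2, abs=1e-9)
        assert f2[0] == pytest.approx(f1[0], abs=1e-6)

    def test_shrinking_arm_increases_force_and_compression(self):
        """Lever-arm mechanism of a COR moved toward a posterior extensor:
        fixed extension demand, shorter arm, strictly larger muscle force
        and joint compression (gravity load + vertical muscle pull)."""
        W = 40.0 * 9.81
        last_f, last_c = -np.inf, -np.inf
        for r in (0.06, 0.05, 0.04, 0.03):
            f, _ = solve_minmax_frame(
                np.array([[r]]), np.array([25.0]), np.array([1000.0])
            )
            compression = W + f[0]
            assert f[0] > last_f and compression > last_c
            last_f, last_c = f[0], compression

    def test_matches_brute_force_oracle_on_random_toys(self):
        rng = np.random.default_rng(2301)
        for _ in range(25):
            A, b, N = random_toy_system(rng)
            f_lp, beta_lp = solve_minmax_frame(A, b, N)
            f_bf, beta_bf = brute_force_minimax(A, b, N)
            assert beta_lp == pytest.approx(beta_bf, abs=1e-6)
            np.testing.assert_allclose(f_lp, f_bf, atol=1e-3)


class TestCycleAndReactions:
    def test_muscle_free_upright_reaction_is_superincumbent_weight(self):
        """No muscle demand: L5S1 reaction = 40*9.81 N = 0.571 BW for a
        70 kg subject."""
        model = lever_model(thorax_x=0.0, thorax_mass=40.0, body_mass=70.0)
        posed = pose_model(model, neutral())
        net = net_loads(posed)
        sol = solve_cycle(posed, net)
        assert np.abs(sol.forces).max() < 1e-6
        assert np.linalg.norm(sol.reactions[0, 0]) == pytest.approx(
            40.0 * 9.81, abs=1e-9
        )
        assert sol.reaction_bw[0, 0] == pytest.approx(40.0 / 70.0, abs=1e-9)

    def test_vertical_extensor_adds_its_pull_to_compression(self):
        """A 500 N vertical extensor on a 40 kg column: L5S1 reaction
        magnitude = 392.4 + 500 = 892.4 N."""
        model = lever_model(
            thorax_x=0.0, thorax_mass=40.0, body_mass=70.0,
            fascicles=[{"name": "ext", "group": "ES_left",
                        "origin": ["pelvis", -0.05, 0.0, 0.0],
                        "insertion": ["thorax", -0.05, 0.2, 0.0],
                        "strength": 1000}],
        )
        posed = pose_model(model, neutral())
        net = net_loads(posed)
        forces = np.zeros((1, len(model.fascicles)))
        forces[0, 0] = 500.0
        reactions = joint_reactions(forces, net, posed)
        assert np.linalg.norm(reactions[0, 0]) == pytest.approx(892.4, abs=1e-9)

    def test_bw_invariant_to_subject_mass_when_loads_are_gravitational(self):
        """Muscle-free reactions in BW depend only on mass fractions."""
        bw = []
        for mass in (50.0, 90.0):
            model = lever_model(
                thorax_x=0.0, thorax_mass=0.4 * mass, body_mass=mass
            )
            posed = pose_model(model, neutral())
            sol = solve_cycle(posed, net_loads(posed))
            bw.append(sol.reaction_bw[0, :5].copy())
        np.testing.assert_allclose(bw[0], bw[1], atol=1e-9)

    def test_reaction_at_least_gravity_when_pulls_compress(self, default_model):
        """On the default geometry the fascicle pulls have a compressive
        component, so reactions can only exceed the gravity load."""
        ang = sl.generate_flexion_task(30.0, n_frames=9)
        posed = pose_model(default_model, ang)
        net = net_loads(posed)
        sol = solve_cycle(posed, net)
        for j, joint in enumerate(sl.JOINTS):
            grav = default_model.superincumbent_mass(joint) * default_model.gravity
            assert (np.linalg.norm(sol.reactions[:, j], axis=1) >= grav - 1e-6).all()

    def test_residual_gate_on_solved_frames(self, ldh_results):
        sol = ldh_results.solution
        demand_scale = 1.0 + np.abs(ldh_results.net.moments[:, :, 2]).max()
        assert sol.residuals.max() <= 1e-6 * demand_scale

    def test_activations_never_exceed_beta(self, ldh_results):
        sol = ldh_results.solution
        assert (sol.activations <= sol.beta[:, None] + 1e-9).all()
        assert (sol.forces >= -1e-12).all()

    def test_frontal_moment_breaks_left_right_symmetry_in_3d(self, default_model):
        ang = sl.generate_flexion_task(20.0, n_frames=5)
        posed = pose_model(default_model, ang)
        extra = np.tile([8.0, 0.0, 0.0], (5, 1))
        sol = solve_cycle(posed, net_loads(posed, extra_moment=extra), axes="3d")
        act = group_activities(sol.activations, default_model)
        assert not np.allclose(act["ES_left"], act["ES_right"], atol=1e-6)


class TestGroupActivities:
    def test_all_zero_activations_give_zero_mmas(self, default_model):
        act = group_activities(
            np.zeros((7, len(default_model.fascicles))), default_model
        )
        assert act.shape == (7, 17)
        assert (act.to_numpy() == 0).all()

    def test_group_activity_is_max_over_member_fascicles(self, default_model):
        rng = np.random.default_rng(9)
        activ = rng.uniform(0, 1, (31, len(default_model.fascicles)))
        act = group_activities(activ, default_model)
        for g in default_model.group_labels:
            members = [
                i for i, f in enumerate(default_model.fascicles) if f.group == g
            ]
            brute = np.max(activ[:, members], axis=1)   # exhaustive frame scan
            np.testing.assert_array_equal(act[g].to_numpy(), brute)
        # and the MMA is the cycle max of the group curve
        assert act["ES_left"].max() == pytest.approx(
            max(
                activ[:, i].max()
                for i, f in enumerate(default_model.fascicles)
                if f.group == "ES_left"
            )
        )
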