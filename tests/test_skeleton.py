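"""Rigid-body model: census, COR offsets, forward kinematics, moment arms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spineload as sl
from spineload.exceptions import SchemaError
from spineload.skeleton import build_default_model, load_model_config, pose_model

from conftest import make_custom_model


def neutral_angles(n=1, rate=100.0):
    return sl.SegmentAngles(np.zeros(n), np.zeros((n, 6)), rate)


class TestCensus:
    def test_seventeen_groups_and_five_reporting_joints(self, default_model):
        assert len(default_model.group_labels) == 17
        assert default_model.lumbar_joints == ("L5S1", "L4L5", "L3L4", "L2L3", "L1L2")
        assert len(default_model.segments) == 7
        assert len(default_model.joints) == 6

    def test_paired_groups_plus_unpaired_ra(self, default_model):
        groups = set(default_model.group_labels)
        assert "RA" in groups
        paired = groups - {"RA"}
        assert len(paired) == 16
        assert all(g.endswith(("_left", "_right")) for g in paired)

    def test_unknown_segment_is_a_schema_error(self, base_config):
        cfg = dict(base_config)
        cfg["fascicles"] = cfg["fascicles"] + [
            {"name": "bogus", "group": "RA",
             "origin": ["L9", 0.0, 0.0, 0.0],
             "insertion": ["thorax", 0.0, 0.1, 0.0], "strength": 100}
        ]
        with pytest.raises(SchemaError, match="L9"):
            build_default_model(cfg)

    @pytest.mark.parametrize(
        "field,value", [("mass_fraction", -0.1), ("mass_fraction", 0.0)]
    )
    def test_nonpositive_mass_rejected(self, field, value):
        cfg = load_model_config()
        cfg["segments"][0][field] = value
        with pytest.raises(SchemaError):
            build_default_model(cfg)

    def test_nonpositive_strength_rejected(self):
        cfg = load_model_config()
        cfg["fascicles"][0]["strength"] = 0.0
        with pytest.raises(SchemaError):
            build_default_model(cfg)

    def test_body_mass_scales_segment_masses(self):
        m60 = build_default_model(body_mass=60.0)
        m90 = build_default_model(body_mass=90.0)
        for a, b in zip(m60.segments, m90.segments):
            assert b.mass == pytest.approx(a.mass * 1.5)


class TestCorOffset:
    def test_zero_offset_is_identity(self, default_model):
        out = sl.apply_cor_offset(default_model, sl.CorOffset(0.0, 0.0))
        for j0, j1 in zip(default_model.joints, out.joints):
            np.testing.assert_array_equal(j0.center, j1.center)

    def test_offsets_cancel(self, default_model):
        out = sl.apply_cor_offset(default_model, sl.CorOffset(-5.0, 0.0))
        out = sl.apply_cor_offset(out, sl.CorOffset(+5.0, 0.0))
        np.testing.assert_allclose(
            out.joints[0].center, default_model.joints[0].center, atol=1e-12
        )

    def test_offset_moves_only_the_named_center(self, default_model):
        out = sl.apply_cor_offset(default_model, sl.CorOffset(-3.0, +2.0, "L5S1"))
        np.testing.assert_allclose(
            out.joints[0].center,
            default_model.joints[0].center + [-0.003, 0.002, 0.0],
            atol=1e-15,
        )
        for j0, j1 in zip(default_model.joints[1:], out.joints[1:]):
            np.testing.assert_array_equal(j0.center, j1.center)
        for f0, f1 in zip(default_model.fascicles, out.fascicles):
            np.testing.assert_array_equal(f0.origin_point, f1.origin_point)
            np.testing.assert_array_equal(f0.insertion_point, f1.insertion_point)

    def test_unknown_level_is_a_key_error(self, default_model):
        with pytest.raises(KeyError):
            sl.apply_cor_offset(default_model, sl.CorOffset(1.0, 0.0, "C7T1"))

    def test_offset_commutes_with_posing_at_zero_angles(self, default_model):
        off = sl.CorOffset(4.0, -6.0)
        posed_then = pose_model(sl.apply_cor_offset(default_model, off), neutral_angles())
        posed_base = pose_model(default_model, neutral_angles())
        np.testing.assert_allclose(
            posed_then.joint_centers[0, 0],
            posed_base.joint_centers[0, 0] + [0.004, -0.006, 0.0],
            atol=1e-15,
        )


class TestPoseModel:
    def test_neutral_pose_matches_config_geometry(self, default_model):
        posed = pose_model(default_model, neutral_angles())
        expect = np.zeros(3)
        for k, joint in enumerate(default_model.joints):
            expect = expect + joint.center
            np.testing.assert_allclose(posed.joint_centers[0, k], expect, atol=1e-15)

    def test_single_joint_rotation_spins_thorax_about_l5s1(self, default_model):
        theta = np.deg2rad(10.0)
        ang = neutral_angles()
        ang.joints[0, 0] = theta
        posed = pose_model(default_model, ang)
        base = pose_model(default_model, neutral_angles())
        c = base.joint_centers[0, 0]
        R = np.array(
            [[np.cos(theta), np.sin(theta), 0.0],
             [-np.sin(theta), np.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        np.testing.assert_allclose(
            posed.coms[0, 6], c + R @ (base.coms[0, 6] - c), atol=1e-12
        )
        np.testing.assert_array_equal(posed.coms[0, 0], base.coms[0, 0])

    @given(
        joints=st.lists(
            st.floats(min_value=-0.5, max_value=0.5), min_size=6, max_size=6
        ),
        pelvis=st.floats(min_value=-0.3, max_value=0.3),
    )
    def test_segment_lengths_rigid_under_any_pose(self, default_model, joints, pelvis):
        ang = sl.SegmentAngles(np.array([pelvis]), np.array([joints]))
        posed = pose_model(default_model, ang)
        neutral = pose_model(default_model, neutral_angles())
        np.testing.assert_allclose(
            posed.segment_lengths(), neutral.segment_lengths(), atol=1e-12
        )

    def test_chain_continuity(self, default_model):
        rng = np.random.default_rng(3)
        ang = sl.SegmentAngles(rng.normal(0, 0.2, 4), rng.normal(0, 0.2, (4, 6)))
        posed = pose_model(default_model, ang)
        assert np.isfinite(posed.joint_centers).all()
        assert np.isfinite(posed.coms).all()
        assert np.isfinite(posed.fasc_lower).all()


class TestMomentArms:
    def test_parallel_fascicle_arm_equals_distance(self):
        d = 0.07
        model = make_custom_model(
            [{"name": "ext", "group": "ES_left",
              "origin": ["pelvis", -d, 0.0, 0.0],
              "insertion": ["thorax", -d, 0.2, 0.0], "strength": 1000}]
        )
        posed = pose_model(model, neutral_angles())
        for joint in sl.JOINTS:
            arms = sl.moment_arms(posed, joint)[0]
            assert arms[0, 2] == pytest.approx(d, abs=1e-12)

    def test_posterior_cor_shift_shortens_lever_by_the_shift(self):
        """Moving the center 5 mm posterior toward a vertical extensor
        shortens its sagittal lever by exactly 5 mm when the muscle line is
        held fixed; the full model relocation (which also carries the
        superincumbent segments and so tilts the line slightly) still
        shortens it, by almost the same amount."""
        import dataclasses

        d = 0.06
        model = make_custom_model(
            [{"name": "ext", "group": "ES_left",
              "origin": ["pelvis", -d, 0.0, 0.0],
              "insertion": ["thorax", -d, 0.2, 0.0], "strength": 1000}]
        )
        posed = pose_model(model, neutral_angles())
        arm0 = sl.moment_arms(posed, "L5S1")[0, 0, 2]
        # frozen muscle geometry, center translated 5 mm posterior
        centers = posed.joint_centers.copy()
        centers[:, 0] += [-0.005, 0.0, 0.0]
        frozen = dataclasses.replace(posed, joint_centers=centers)
        assert arm0 - sl.moment_arms(frozen, "L5S1")[0, 0, 2] == pytest.approx(
            0.005, abs=1e-12
        )
        # end-to-end relocation: shorter lever, within the tilt correction
        shifted = sl.apply_cor_offset(model, sl.CorOffset(ap=-5.0, si=0.0))
        arm1 = sl.moment_arms(pose_model(shifted, neutral_angles()), "L5S1")[0, 0, 2]
        assert 0.003 < arm0 - arm1 < 0.005

    def test_noncrossing_fascicles_contribute_zero(self, default_model):
        posed = pose_model(default_model, neutral_angles())
        arms = sl.moment_arms(posed, "T12L1")[0]
        for i, f in enumerate(default_model.fascicles):
            if not posed.crossing[i, 5]:
                np.testing.assert_array_equal(arms[i], 0.0)

    def test_geometric_arms_match_tendon_excursion(self, default_model):
        """Sagittal moment arms equal dL/dtheta by virtual work (the sign
        is positive because extension moments and flexion angles are
        measured about opposite senses of the Z axis)."""
        rng = np.random.default_rng(7)
        joints = rng.uniform(-0.15, 0.15, (1, 6))
        pelvis = rng.uniform(-0.1, 0.1, 1)
        h = 1e-6
        for jidx, jname in enumerate(sl.JOINTS):
            posed = pose_model(default_model, sl.SegmentAngles(pelvis, joints))
            arms = sl.moment_arms(posed, jname)[0]
            jp, jm = joints.copy(), joints.copy()
            jp[0, jidx] += h
            jm[0, jidx] -= h
            Lp = pose_model(default_model, sl.SegmentAngles(pelvis, jp)).fascicle_lengths()[0]
            Lm = pose_model(default_model, sl.SegmentAngles(pelvis, jm)).fascicle_lengths()[0]
            dL = (Lp - Lm) / (2 * h)
            np.testing.assert_allclose(arms[:, 2], dL, atol=1e-6)
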