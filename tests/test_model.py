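"""Model structure, kinematics, muscle-tendon geometry and Hill scalars."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femgait.errors import ParameterError
from femgait.geometry import rotation_about_axis
from femgait.model import (Muscle, MuscleParams, MusclePath, Posture,
                           force_scalars, force_velocity, forward_kinematics,
                           model_from_dict, model_to_dict, moment_arm,
                           mtu_length, mtu_lengths_batch,
                           recalibrate_muscle_parameters, reference_posture)
from femgait.template import anatomical_fmax_sum, build_template_model

from conftest import make_hinge_model

NAMED_MUSCLES = {"glut_med", "glut_min", "glut_max", "iliacus", "psoas",
                 "tfl", "piriformis", "rect_fem", "vasti", "semimem",
                 "bflh", "bfsh", "add_mag", "gracilis", "gastroc", "soleus",
                 "tib_ant"}


class TestTemplate:
    def test_structure(self, template_model):
        m = template_model
        assert len(m.dof_names) == 5
        hip = next(j for j in m.joints if j.name == "hip")
        knee = next(j for j in m.joints if j.name == "knee")
        ankle = next(j for j in m.joints if j.name == "ankle")
        assert (len(hip.dofs), len(knee.dofs), len(ankle.dofs)) == (3, 1, 1)
        assert m.segment_order() == ["pelvis", "femur", "tibia", "foot"]
        assert len(m.muscles) >= 16
        assert NAMED_MUSCLES <= set(m.muscle_names)

    def test_fmax_scaling(self):
        doubled = build_template_model(73.1, 1.71, 2.0)
        plain = build_template_model(73.1, 1.71, 1.0)
        total = sum(mm.params.f_max for mm in doubled.muscles)
        anatomical = sum(mm.params.f_max for mm in plain.muscles)
        assert total == pytest.approx(2.0 * anatomical, rel=1e-12)
        assert anatomical == pytest.approx(anatomical_fmax_sum(), rel=1e-12)

    def test_anthropometric_scaling(self):
        a = build_template_model(73.1, 1.71, 1.0)
        b = build_template_model(2 * 73.1, 1.71 * 1.1, 1.0)
        assert b.segments["femur"].mass == pytest.approx(
            2 * a.segments["femur"].mass)
        assert np.allclose(b.joints[1].location_in_parent,
                           1.1 * a.joints[1].location_in_parent)

    @pytest.mark.parametrize("bad", [(0, 1.71, 2), (73.1, -1, 2),
                                     (73.1, 1.71, 0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ParameterError):
            build_template_model(*bad)

    def test_json_round_trip(self, template_model):
        d = model_to_dict(template_model)
        m2 = model_from_dict(d)
        assert m2.muscle_names == template_model.muscle_names
        q = reference_posture(template_model).q_vector(template_model)
        assert np.allclose(mtu_lengths_batch(m2, q[None, :]),
                           mtu_lengths_batch(template_model, q[None, :]),
                           atol=1e-15)

    def test_unknown_schema_rejected(self, template_model):
        d = model_to_dict(template_model)
        d["schema_version"] = "99.0"
        from femgait.errors import FormatError
        with pytest.raises(FormatError):
            model_from_dict(d)


class TestForwardKinematics:
    def test_zero_posture_is_reference(self, template_model):
        pos = forward_kinematics(template_model,
                                 reference_posture(template_model))
        # at all angles zero, world = accumulated joint offsets + local
        hip = template_model.joints[0].location_in_parent
        origin = template_model.muscle("glut_med").path.points[0][1]
        assert np.allclose(pos["glut_med[0]"], origin, atol=1e-15)
        insertion = template_model.muscle("glut_med").path.points[1][1]
        assert np.allclose(pos["glut_med[1]"], hip + insertion, atol=1e-15)

    def test_pelvis_point_invariant_under_hip_angle(self, template_model):
        p0 = forward_kinematics(template_model,
                                reference_posture(template_model))
        post = reference_posture(template_model)
        post.angles["hip_flexion"] = 47.0
        post.angles["hip_abduction"] = -12.0
        p1 = forward_kinematics(template_model, post)
        assert np.allclose(p0["glut_med[0]"], p1["glut_med[0]"], atol=1e-15)

    def test_hip_flexion_rotates_knee_center(self, template_model):
        """90 deg hip flexion moves the knee center by a hand-computed
        single-axis rotation about the hip flexion axis."""
        m = template_model
        post = reference_posture(m)
        post.angles["hip_flexion"] = 90.0
        pos = forward_kinematics(m, post)
        hip_w = m.joints[0].location_in_parent
        knee_local = m.joints[1].location_in_parent
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        expected_tibia_origin = hip_w + R @ knee_local
        # rect_fem insertion sits on the tibia; check through it
        ins_local = m.muscle("rect_fem").path.points[-1][1]
        assert np.allclose(pos["rect_fem[2]"],
                           expected_tibia_origin + R @ ins_local, atol=1e-12)

    def test_missing_dof_errors(self, template_model):
        with pytest.raises(ParameterError):
            forward_kinematics(template_model, Posture({"hip_flexion": 0.0}))


class TestMtuLength:
    def test_three_four_five(self):
        m = make_hinge_model(origin=(0.0, 0.0, 0.0), insertion=(0.3, 0.0, 0.4))
        assert mtu_length(m, Posture({"hip_flexion": 0.0}), "toy") == \
            pytest.approx(0.5, abs=1e-14)

    def test_collinear_via_point_invariance(self):
        m = make_hinge_model(origin=(0.0, 0.0, 0.0), insertion=(0.3, 0.0, 0.4))
        m2 = make_hinge_model(origin=(0.0, 0.0, 0.0), insertion=(0.3, 0.0, 0.4))
        mid = np.array([0.15, 0.0, 0.2])
        m2.muscles[0] = Muscle("toy", MusclePath(
            [("pelvis", np.zeros(3)), ("femur", mid),
             ("femur", np.array([0.3, 0.0, 0.4]))]),
            MuscleParams(f_max=400, l_opt=0.2, l_slack=0.1))
        for ang in (0.0, 17.0, -40.0):
            p = Posture({"hip_flexion": ang})
            assert mtu_length(m2, p, "toy") == \
                pytest.approx(mtu_length(m, p, "toy"), abs=1e-12)

    def test_unknown_muscle(self, template_model):
        with pytest.raises(KeyError):
            mtu_length(template_model, reference_posture(template_model),
                       "nope")

    def test_length_continuity_over_grid(self, template_model):
        """No frame-to-frame jumps beyond the bound implied by path-point
        speed (smooth muscle-tendon kinematics)."""
        q0 = np.zeros(5)
        grid = np.linspace(-20, 60, 200)
        Q = np.tile(q0, (200, 1))
        Q[:, 0] = grid
        L = mtu_lengths_batch(template_model, Q)
        dq = np.deg2rad(grid[1] - grid[0])
        # every path point is within ~0.6 m of the hip, so |dL/dq| < 1.2 m
        assert np.max(np.abs(np.diff(L, axis=0))) < 1.2 * dq


class TestMomentArm:
    def test_perpendicular_distance(self):
        # line from (0, 0.05) parallel to x: perpendicular distance 0.05
        m = make_hinge_model(origin=(-0.2, 0.05, 0.0),
                             insertion=(0.2, 0.05, 0.0))
        r = moment_arm(m, Posture({"hip_flexion": 0.0}), "toy", "hip_flexion")
        assert abs(r) == pytest.approx(0.05, abs=1e-6)

    def test_random_postures_match_geometric_oracle(self):
        """Tendon-excursion arm equals the point-to-line perpendicular
        distance on a planar hinge across 100 random postures."""
        rng = np.random.default_rng(42)
        m = make_hinge_model(origin=(-0.15, 0.08, 0.0),
                             insertion=(0.12, -0.18, 0.0))
        for _ in range(100):
            ang = rng.uniform(-80, 80)
            post = Posture({"hip_flexion": ang})
            r = moment_arm(m, post, "toy", "hip_flexion")
            pos = forward_kinematics(m, post)
            a, b = pos["toy[0]"], pos["toy[1]"]
            u = (b - a) / np.linalg.norm(b - a)
            dist = np.linalg.norm(np.cross(-a, u))
            assert abs(abs(r) - dist) < 1e-4

    def test_non_crossing_muscle_is_zero(self, template_model):
        # soleus does not cross the hip
        r = moment_arm(template_model, reference_posture(template_model),
                       "soleus", "hip_flexion")
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_insertion_negates(self):
        m1 = make_hinge_model(origin=(-0.2, 0.05, 0.0),
                              insertion=(0.2, 0.05, 0.0))
        m2 = make_hinge_model(origin=(-0.2, -0.05, 0.0),
                              insertion=(0.2, -0.05, 0.0))
        p = Posture({"hip_flexion": 0.0})
        r1 = moment_arm(m1, p, "toy", "hip_flexion")
        r2 = moment_arm(m2, p, "toy", "hip_flexion")
        assert r1 == pytest.approx(-r2, abs=1e-9)

    def test_stencil_clamped_near_limit(self):
        m = make_hinge_model()
        m.joints[0].dofs[0].range_deg = (-10.0, 0.0)
        with pytest.warns(UserWarning, match="clamped"):
            moment_arm(m, Posture({"hip_flexion": 0.0}), "toy", "hip_flexion")


class TestForceScalars:
    def test_anchors(self):
        f_l, f_v = force_scalars(1.0, 0.0)
        assert (f_l, f_v) == (pytest.approx(1.0), pytest.approx(1.0))
        assert force_scalars(1.0, -1.0)[1] == pytest.approx(0.0, abs=1e-14)
        w = 0.45
        assert force_scalars(1.0 + w, 0.0, fl_width=w)[0] == \
            pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_negative_fiber_length_warns_zero(self):
        with pytest.warns(UserWarning):
            f_l, _ = force_scalars(-0.2, 0.0)
        assert f_l == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-3.0, 3.0), st.floats(-3.0, 3.0))
    def test_fv_monotone_and_bounded(self, v1, v2):
        f1, f2 = force_velocity(v1), force_velocity(v2)
        if v1 <= v2:
            assert f1 <= f2 + 1e-12
        assert 0.0 <= f1 <= 1.4 + 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.0, 2.5))
    def test_fl_maximal_at_optimum(self, l):
        assert force_scalars(l, 0.0)[0] <= force_scalars(1.0, 0.0)[0]

    def test_fv_continuous_at_zero(self):
        eps = 1e-9
        assert abs(force_velocity(eps) - force_velocity(-eps)) < 1e-6


class TestRecalibration:
    def test_identity(self, template_model):
        out = recalibrate_muscle_parameters(
            template_model, reference_posture(template_model), template_model)
        for a, b in zip(out.muscles, template_model.muscles):
            assert a.params.l_opt == pytest.approx(b.params.l_opt, rel=1e-12)
            assert a.params.l_slack == pytest.approx(b.params.l_slack,
                                                     rel=1e-12)

    def test_two_percent_stretch(self):
        ref = make_hinge_model(origin=(0.0, 0.0, 0.0),
                               insertion=(0.3, 0.0, 0.4))
        stretched = make_hinge_model(origin=(0.0, 0.0, 0.0),
                                     insertion=(0.306, 0.0, 0.408))
        out = recalibrate_muscle_parameters(
            stretched, Posture({"hip_flexion": 0.0}), ref)
        assert out.muscles[0].params.l_opt == pytest.approx(0.2 * 1.02,
                                                            rel=1e-12)
        assert out.muscles[0].params.l_slack == pytest.approx(0.1 * 1.02,
                                                              rel=1e-12)

    def test_normalized_fiber_length_preserved(self, template_model):
        from femgait.torsion import GeometryTarget, apply_deformation
        ref = template_model
        post = reference_posture(ref)
        deformed = apply_deformation(ref, GeometryTarget(48.0, 153.0))
        recal = recalibrate_muscle_parameters(deformed, post, ref)
        q = post.q_vector(ref)[None, :]
        L_ref = mtu_lengths_batch(ref, q)[0]
        L_new = mtu_lengths_batch(recal, q)[0]
        for i, m in enumerate(recal.muscles):
            ln_ref = (L_ref[i] - ref.muscles[i].params.l_slack) / \
                ref.muscles[i].params.l_opt
            ln_new = (L_new[i] - m.params.l_slack) / m.params.l_opt
            assert ln_new == pytest.approx(ln_ref, abs=1e-9)

    def test_idempotent(self, template_model):
        post = reference_posture(template_model)
        once = recalibrate_muscle_parameters(template_model, post,
                                             template_model)
        twice = recalibrate_muscle_parameters(once, post, template_model)
        for a, b in zip(twice.muscles, once.muscles):
            assert a.params.l_opt == pytest.approx(b.params.l_opt, rel=1e-12)
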