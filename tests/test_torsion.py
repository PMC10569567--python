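"""Femoral geometry measurement, deformation and the factorial sweep."""

import itertools

import numpy as np
import pytest

from femgait.errors import (ConfigurationError, DegenerateGeometryError,
                            ParameterError)
from femgait.geometry import rotation_about_axis
from femgait.model import FemoralLandmarks
from femgait.torsion import (GeometryTarget, SweepSpec, apply_deformation,
                             generate_sweep, measure_ava, measure_nsa)

from conftest import dummy_landmarks


def rotate_landmarks(lm: FemoralLandmarks, axis, angle,
                     shift=(0.0, 0.0, 0.0)) -> FemoralLandmarks:
    R = rotation_about_axis(np.asarray(axis, float), angle)
    s = np.asarray(shift)
    return FemoralLandmarks(*[R @ p + s for p in lm.as_array()])


class TestMeasurement:
    def test_template_reference_values(self, template_model):
        assert measure_ava(template_model.landmarks) == pytest.approx(
            18.0, abs=1e-9)
        assert measure_nsa(template_model.landmarks) == pytest.approx(
            123.0, abs=1e-9)

    def test_perpendicular_anterior_neck_is_90(self, template_model):
        lm = template_model.landmarks
        # neck projecting along anterior (+X), shaft +Y, condyles along Z
        lm2 = FemoralLandmarks(
            head_center=lm.neck_base + np.array([0.05, -0.02, 0.0]),
            neck_base=lm.neck_base, shaft_proximal=lm.shaft_proximal,
            shaft_distal=lm.shaft_distal,
            epicondyle_medial=lm.epicondyle_medial,
            epicondyle_lateral=lm.epicondyle_lateral)
        assert measure_ava(lm2) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_head_gives_zero_nsa(self, template_model):
        lm = template_model.landmarks
        s = lm.shaft_proximal - lm.shaft_distal
        lm2 = FemoralLandmarks(
            head_center=lm.neck_base + 0.05 * s / np.linalg.norm(s),
            neck_base=lm.neck_base, shaft_proximal=lm.shaft_proximal,
            shaft_distal=lm.shaft_distal,
            epicondyle_medial=lm.epicondyle_medial,
            epicondyle_lateral=lm.epicondyle_lateral)
        assert measure_nsa(lm2) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_rotation_invariance(self, template_model, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        lm2 = rotate_landmarks(template_model.landmarks, axis,
                               rng.uniform(-np.pi, np.pi),
                               shift=rng.normal(size=3) * 0.1)
        assert measure_ava(lm2) == pytest.approx(18.0, abs=1e-9)
        assert measure_nsa(lm2) == pytest.approx(123.0, abs=1e-9)

    def test_degenerate_neck_parallel_to_shaft(self, template_model):
        lm = template_model.landmarks
        s = lm.shaft_proximal - lm.shaft_distal
        lm2 = FemoralLandmarks(
            head_center=lm.neck_base + 0.05 * s / np.linalg.norm(s),
            neck_base=lm.neck_base, shaft_proximal=lm.shaft_proximal,
            shaft_distal=lm.shaft_distal,
            epicondyle_medial=lm.epicondyle_medial,
            epicondyle_lateral=lm.epicondyle_lateral)
        with pytest.raises(DegenerateGeometryError):
            measure_ava(lm2)


class TestDeformation:
    def test_reference_target_is_identity(self, template_model):
        out = apply_deformation(template_model, GeometryTarget(18.0, 123.0))
        for m_out, m_ref in zip(out.muscles, template_model.muscles):
            for (s1, p1), (s2, p2) in zip(m_out.path.points,
                                          m_ref.path.points):
                assert s1 == s2
                assert np.array_equal(p1, p2)
        assert np.array_equal(out.landmarks.as_array(),
                              template_model.landmarks.as_array())

    @pytest.mark.parametrize("ava,nsa", [(48.0, 123.0), (18.0, 153.0),
                                         (-12.0, 93.0), (48.0, 153.0)])
    def test_targets_hit(self, template_model, ava, nsa):
        out = apply_deformation(template_model, GeometryTarget(ava, nsa))
        assert measure_ava(out.landmarks) == pytest.approx(ava, abs=0.1)
        assert measure_nsa(out.landmarks) == pytest.approx(nsa, abs=0.1)

    def test_rigidity_of_deformed_region(self, template_model):
        """Pairwise distances among deformed femur points are preserved."""
        out = apply_deformation(template_model, GeometryTarget(48.0, 153.0))

        def femur_points(model):
            pts = [p for m in model.muscles
                   for seg, p in m.path.points if seg == "femur"]
            return np.array(pts + list(model.landmarks.as_array()))

        a, b = femur_points(template_model), femur_points(out)
        d_a = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=2)
        d_b = np.linalg.norm(b[:, None, :] - b[None, :, :], axis=2)
        # restrict to point pairs inside the deformed (moved) region
        moved = np.any(a != b, axis=1)
        assert np.max(np.abs(d_a[np.ix_(moved, moved)]
                             - d_b[np.ix_(moved, moved)])) < 1e-9

    def test_joints_and_inertia_untouched(self, template_model):
        out = apply_deformation(template_model, GeometryTarget(48.0, 153.0))
        for j_out, j_ref in zip(out.joints, template_model.joints):
            assert np.array_equal(j_out.location_in_parent,
                                  j_ref.location_in_parent)
        for name in template_model.segments:
            assert out.segments[name].mass == template_model.segments[name].mass
            assert np.array_equal(out.segments[name].inertia,
                                  template_model.segments[name].inertia)
            assert np.array_equal(out.segments[name].com,
                                  template_model.segments[name].com)

    def test_round_trip_over_random_grid(self, template_model):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = GeometryTarget(rng.uniform(-40, 60), rng.uniform(95, 160))
            out = apply_deformation(template_model, t)
            assert abs(measure_ava(out.landmarks) - t.ava) < 0.1
            assert abs(measure_nsa(out.landmarks) - t.nsa) < 0.1

    def test_deformations_commute_in_measurement(self, template_model):
        a = apply_deformation(
            apply_deformation(template_model, GeometryTarget(48.0, 123.0)),
            GeometryTarget(48.0, 153.0))
        b = apply_deformation(
            apply_deformation(template_model, GeometryTarget(18.0, 153.0)),
            GeometryTarget(48.0, 153.0))
        assert abs(measure_ava(a.landmarks) - measure_ava(b.landmarks)) < 0.1
        assert abs(measure_nsa(a.landmarks) - measure_nsa(b.landmarks)) < 0.1

    def test_region_must_contain_neck_base(self, template_model):
        with pytest.raises(ConfigurationError):
            apply_deformation(template_model, GeometryTarget(48.0, 123.0),
                              region_fraction=-0.1)

    def test_target_validation(self):
        with pytest.raises(ParameterError):
            GeometryTarget(95.0, 123.0)
        with pytest.raises(ParameterError):
            GeometryTarget(18.0, 60.0)


class TestSweep:
    def test_default_sweep_is_25_models(self, template_model):
        spec = SweepSpec(reference=GeometryTarget(18.0, 123.0))
        sweep = generate_sweep(template_model, spec)
        assert len(sweep) == 25
        measured = {(round(measure_ava(m.landmarks), 3),
                     round(measure_nsa(m.landmarks), 3))
                    for _, m in sweep}
        expected = set(itertools.product((-12.0, 3.0, 18.0, 33.0, 48.0),
                                         (93.0, 108.0, 123.0, 138.0, 153.0)))
        for ava, nsa in expected:
            assert any(abs(a - ava) < 0.1 and abs(n - nsa) < 0.1
                       for a, n in measured)

    def test_zero_offset_sweep_is_identity(self, template_model):
        spec = SweepSpec(reference=GeometryTarget(18.0, 123.0),
                         offsets=(0.0,))
        sweep = generate_sweep(template_model, spec)
        assert len(sweep) == 1
        _, m = sweep[0]
        for m_out, m_ref in zip(m.muscles, template_model.muscles):
            for (_, p1), (_, p2) in zip(m_out.path.points, m_ref.path.points):
                assert np.allclose(p1, p2, atol=1e-15)

    def test_duplicate_offsets_collapse(self, template_model):
        with pytest.warns(UserWarning, match="de-duplicated"):
            spec = SweepSpec(reference=GeometryTarget(18.0, 123.0),
                             offsets=(0.0, 0.0, 15.0))
        sweep = generate_sweep(template_model, spec)
        assert len(sweep) == 4  # {18,33} x {123,138}
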