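import numpy as np
import pytest

from femgait.gait import GaitTrial, normalize_to_cycle, synthesize_trial
from femgait.model import (DoF, FemoralLandmarks, Joint, Model, Muscle,
                           MuscleParams, MusclePath, Posture, Segment)
from femgait.study import StudyConfig, run_study
from femgait.template import build_template_model


def dummy_landmarks() -> FemoralLandmarks:
    """Valid landmark set for toy models that do not exercise morphing."""
    return FemoralLandmarks(
        head_center=np.array([0.02, -0.04, -0.02]),
        neck_base=np.array([0.0, -0.01, 0.03]),
        shaft_proximal=np.array([0.0, -0.01, 0.03]),
        shaft_distal=np.array([0.0, -0.38, 0.03]),
        epicondyle_medial=np.array([0.0, -0.38, -0.01]),
        epicondyle_lateral=np.array([0.0, -0.38, 0.07]))


def make_hinge_model(origin=(-0.1, 0.1, 0.0), insertion=(0.1, -0.2, 0.0),
                     axis=(0.0, 0.0, 1.0), f_max=400.0,
                     femur_mass=5.0, femur_com=(0.0, -0.15, 0.0)):
    """Pelvis + femur with a single hinge at the origin and one straight
    two-point muscle from pelvis to femur."""
    segments = {
        "pelvis": Segment("pelvis", 10.0, np.zeros(3), np.eye(3) * 0.1),
        "femur": Segment("femur", femur_mass, np.array(femur_com),
                         np.eye(3) * 0.05),
    }
    joints = [Joint("hip", "pelvis", "femur", np.zeros(3),
                    [DoF("hip_flexion", np.array(axis, dtype=float))])]
    muscles = [Muscle("toy", MusclePath([("pelvis", np.array(origin)),
                                         ("femur", np.array(insertion))]),
                      MuscleParams(f_max=f_max, l_opt=0.2, l_slack=0.1))]
    return Model(segments=segments, joints=joints, muscles=muscles,
                 landmarks=dummy_landmarks(), subject_mass=15.0,
                 subject_height=1.0)


def constant_trial(model: Model, n: int = 5, duration: float = 1.0,
                   grf: float = 0.0) -> GaitTrial:
    """Trial with all angles zero and constant (possibly zero) GRF."""
    time = np.linspace(0.0, duration, n)
    angles = {d: np.zeros(n) for d in model.dof_names}
    g = np.zeros((n, 3))
    g[:, 1] = grf
    return GaitTrial(time=time, angles=angles, grf=g, cop=np.zeros((n, 3)),
                     foot_strike=0.0, foot_off=0.6 * duration,
                     next_foot_strike=duration,
                     subject_mass=model.subject_mass)


@pytest.fixture(scope="session")
def template_model():
    return build_template_model(73.1, 1.71, 2.0)


@pytest.fixture(scope="session")
def default_trial():
    raw = synthesize_trial(seed=0)
    cyc = normalize_to_cycle(raw)
    return GaitTrial(time=cyc.time, angles=cyc.angles, grf=cyc.grf,
                     cop=cyc.cop, foot_strike=raw.foot_strike,
                     foot_off=raw.foot_off,
                     next_foot_strike=raw.next_foot_strike,
                     subject_mass=raw.subject_mass,
                     walking_velocity=raw.walking_velocity)


@pytest.fixture(scope="session")
def study_result():
    """The full default 25-model study (shared across tests; ~3 s)."""
    return run_study(StudyConfig(seed=1))
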