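"""Author the packaged template model fixture.

Constructs the template anatomy (native anthropometry 75.16 kg / 1.80 m,
right leg) from literal coordinates adapted from published gait-model
anatomy, computes each muscle's tendon slack length so that the normalized
fiber length is exactly 1 at the anatomical zero posture, verifies the
femoral landmark angles (AVA 18 deg, NSA 123 deg), and writes the versioned
JSON fixture consumed by ``femgait.template.build_template_model``.

Run from the repository root:  python scripts/build_template_fixture.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from femgait.model import (DoF, FemoralLandmarks, Joint, Model, Muscle,
                           MuscleParams, MusclePath, Segment, model_to_dict,
                           mtu_lengths_batch, reference_posture)
from femgait.torsion import measure_ava, measure_nsa

OUT = Path(__file__).resolve().parents[1] / "src/femgait/data/template_model.json"

AVA_REF = 18.0   # deg
NSA_REF = 123.0  # deg
NECK_LENGTH = 0.060  # m

SEGMENTS = {
    "pelvis": dict(mass=11.777, com=[-0.0707, 0.0, 0.0],
                   inertia=[0.1028, 0.0871, 0.0579]),
    "femur": dict(mass=9.3014, com=[0.0, -0.170, 0.0],
                  inertia=[0.1339, 0.0351, 0.1412]),
    "tibia": dict(mass=3.7075, com=[0.0, -0.1867, 0.0],
                  inertia=[0.0504, 0.0051, 0.0511]),
    "foot": dict(mass=1.5666, com=[0.05, -0.035, 0.0],
                 inertia=[0.0014, 0.0039, 0.0041]),
}

JOINTS = [
    ("hip", "pelvis", "femur", [-0.0707, -0.0661, 0.0835], [
        ("hip_flexion", [0, 0, 1], (-30, 130)),
        ("hip_abduction", [-1, 0, 0], (-50, 50)),
        ("hip_rotation", [0, 1, 0], (-50, 50)),
    ]),
    ("knee", "femur", "tibia", [-0.0045, -0.396, 0.0], [
        ("knee_flexion", [0, 0, -1], (-10, 140)),
    ]),
    ("ankle", "tibia", "foot", [0.0, -0.430, 0.0], [
        ("ankle_dorsiflexion", [0, 0, 1], (-50, 40)),
    ]),
]

# name, f_max (N), l_opt (m), path [(segment, xyz)], spanned joints
MUSCLES = [
    ("glut_med", 2045.0, 0.100,
     [("pelvis", [-0.041, 0.030, 0.120]), ("femur", [-0.022, -0.012, 0.055])],
     ("hip",)),
    ("glut_min", 585.0, 0.060,
     [("pelvis", [-0.047, -0.008, 0.106]), ("femur", [-0.005, -0.012, 0.056])],
     ("hip",)),
    ("glut_max", 1700.0, 0.140,
     [("pelvis", [-0.130, 0.020, 0.056]), ("femur", [-0.046, -0.025, 0.039]),
      ("femur", [-0.028, -0.057, 0.047])],
     ("hip",)),
    ("iliacus", 1073.0, 0.100,
     [("pelvis", [-0.067, 0.037, 0.085]), ("pelvis", [-0.032, -0.065, 0.082]),
      ("femur", [-0.019, -0.062, 0.013])],
     ("hip",)),
    ("psoas", 1113.0, 0.100,
     [("pelvis", [-0.065, 0.089, 0.029]), ("pelvis", [-0.035, -0.065, 0.075]),
      ("femur", [-0.019, -0.060, 0.010])],
     ("hip",)),
    ("tfl", 233.0, 0.095,
     [("pelvis", [-0.031, 0.021, 0.124]), ("femur", [0.005, -0.035, 0.062]),
      ("femur", [0.006, -0.340, 0.049]), ("tibia", [0.010, -0.040, 0.030])],
     ("hip", "knee")),
    ("piriformis", 296.0, 0.080,
     [("pelvis", [-0.140, 0.000, 0.024]), ("femur", [-0.015, -0.002, 0.044])],
     ("hip",)),
    ("rect_fem", 1169.0, 0.110,
     [("pelvis", [-0.030, -0.031, 0.097]), ("femur", [0.040, -0.360, 0.002]),
      ("tibia", [0.039, -0.082, 0.000])],
     ("hip", "knee")),
    ("vasti", 4530.0, 0.100,
     [("femur", [0.029, -0.190, 0.031]), ("femur", [0.040, -0.372, 0.002]),
      ("tibia", [0.039, -0.082, 0.000])],
     ("knee",)),
    ("semimem", 1288.0, 0.110,
     [("pelvis", [-0.119, -0.097, 0.069]), ("femur", [-0.028, -0.370, -0.012]),
      ("tibia", [-0.024, -0.054, -0.019])],
     ("hip", "knee")),
    ("bflh", 896.0, 0.110,
     [("pelvis", [-0.126, -0.103, 0.069]), ("femur", [-0.028, -0.370, 0.028]),
      ("tibia", [-0.022, -0.056, 0.035])],
     ("hip", "knee")),
    ("bfsh", 804.0, 0.120,
     [("femur", [-0.023, -0.300, 0.026]), ("tibia", [-0.022, -0.056, 0.035])],
     ("knee",)),
    ("add_mag", 1102.0, 0.130,
     [("pelvis", [-0.083, -0.119, 0.031]), ("femur", [-0.004, -0.250, 0.010])],
     ("hip",)),
    ("gracilis", 162.0, 0.170,
     [("pelvis", [-0.056, -0.124, 0.010]), ("femur", [-0.012, -0.370, -0.022]),
      ("tibia", [-0.002, -0.080, -0.018])],
     ("hip", "knee")),
    ("gastroc", 2241.0, 0.090,
     [("femur", [-0.024, -0.360, 0.009]), ("tibia", [-0.030, -0.200, 0.007]),
      ("foot", [-0.044, -0.038, 0.002])],
     ("knee", "ankle")),
    ("soleus", 3549.0, 0.080,
     [("tibia", [-0.024, -0.150, 0.007]), ("foot", [-0.044, -0.038, 0.002])],
     ("ankle",)),
    ("tib_ant", 905.0, 0.100,
     [("tibia", [0.018, -0.160, 0.012]), ("tibia", [0.030, -0.400, -0.010]),
      ("foot", [0.060, -0.020, -0.015])],
     ("ankle",)),
]


def landmarks() -> FemoralLandmarks:
    neck_base = np.array([0.0, -0.010, 0.036])
    shaft_distal = np.array([0.0, -0.380, 0.036])
    # neck direction: NSA from the proximal shaft direction (+Y), transverse
    # component tilted AVA degrees anterior of the condylar (+/-Z) line
    nsa, ava = np.deg2rad(NSA_REF), np.deg2rad(AVA_REF)
    n = np.array([np.sin(nsa) * np.sin(ava),
                  np.cos(nsa),
                  -np.sin(nsa) * np.cos(ava)])
    return FemoralLandmarks(
        head_center=neck_base + NECK_LENGTH * n,
        neck_base=neck_base,
        shaft_proximal=neck_base.copy(),
        shaft_distal=shaft_distal,
        epicondyle_medial=np.array([0.0, -0.380, -0.004]),
        epicondyle_lateral=np.array([0.0, -0.380, 0.076]),
    )


def build() -> Model:
    segments = {n: Segment(n, d["mass"], np.array(d["com"]),
                           np.diag(d["inertia"]))
                for n, d in SEGMENTS.items()}
    joints = [Joint(n, p, c, np.array(loc),
                    [DoF(dn, np.array(ax, dtype=float), rng)
                     for dn, ax, rng in dofs])
              for n, p, c, loc, dofs in JOINTS]
    muscles = [Muscle(n, MusclePath([(s, np.array(p)) for s, p in path]),
                      MuscleParams(f_max=fmax, l_opt=lopt, l_slack=1.0),
                      spans)
               for n, fmax, lopt, path, spans in MUSCLES]
    model = Model(segments=segments, joints=joints, muscles=muscles,
                  landmarks=landmarks(), subject_mass=75.16,
                  subject_height=1.80, fmax_scale=1.0,
                  meta={"template": "femgait-lowerlimb", "version": "1.0",
                        "side": "right"})
    # tendon slack so normalized fiber length = 1 at the zero posture
    L = mtu_lengths_batch(model, reference_posture(model).q_vector(model)[None, :])[0]
    for i, m in enumerate(model.muscles):
        slack = L[i] - m.params.l_opt
        if slack < 0.005:
            raise SystemExit(
                f"{m.name}: tendon slack {slack:.4f} m too small "
                f"(MTU length {L[i]:.4f}); reduce l_opt")
        m.params.l_slack = float(slack)
    return model


def main():
    model = build()
    ava, nsa = measure_ava(model.landmarks), measure_nsa(model.landmarks)
    print(f"measured AVA {ava:.6f} deg, NSA {nsa:.6f} deg")
    assert abs(ava - AVA_REF) < 1e-9 and abs(nsa - NSA_REF) < 1e-9
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(model_to_dict(model), indent=1))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
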