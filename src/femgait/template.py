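"""The packaged lower-limb template model.

A simplified single-leg (right) model — pelvis (base), femur (3-DOF hip),
tibia (1-DOF knee), foot (1-DOF ankle) — with 17 muscle-tendon units whose
attachment coordinates, masses and inertias are adapted from published
gait-model anatomy.  The reference femur measures an anteversion angle of
18 deg and a neck-shaft angle of 123 deg exactly.  The template is stored
as a versioned JSON fixture at its native anthropometry (75.16 kg, 1.80 m)
and scaled to the subject: masses with subject mass, all lengths (segment
geometry, muscle attachments, fiber/tendon lengths) with subject height,
inertias with mass x height^2.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

from .errors import ParameterError
from .model import Model, model_from_dict

import json

#: anthropometry at which the template fixture is stored
TEMPLATE_MASS = 75.16  # kg
TEMPLATE_HEIGHT = 1.80  # m


def _load_template_dict() -> dict:
    ref = importlib.resources.files("femgait").joinpath(
        "data/template_model.json")
    return json.loads(ref.read_text())


def build_template_model(subject_mass: float = 73.1,
                         subject_height: float = 1.71,
                         fmax_scale: float = 2.0) -> Model:
    """Build the packaged template scaled to a subject.

    ``fmax_scale`` multiplies every muscle's maximum isometric force; the
    default of 2 reflects the adjustment needed to keep activations away
    from the 100% plateau for a heavy, fast-walking adult.
    """
    if subject_mass <= 0 or subject_height <= 0 or fmax_scale <= 0:
        raise ParameterError(
            "subject_mass, subject_height and fmax_scale must be positive")
    model = model_from_dict(_load_template_dict())
    mf = subject_mass / TEMPLATE_MASS
    sf = subject_height / TEMPLATE_HEIGHT
    for s in model.segments.values():
        s.mass *= mf
        s.com = s.com * sf
        s.inertia = s.inertia * (mf * sf * sf)
    for j in model.joints:
        j.location_in_parent = j.location_in_parent * sf
    for m in model.muscles:
        m.path.points = [(seg, p * sf) for seg, p in m.path.points]
        m.params.l_opt *= sf
        m.params.l_slack *= sf
        m.params.f_max *= fmax_scale
    lm = model.landmarks
    for f in ("head_center", "neck_base", "shaft_proximal", "shaft_distal",
              "epicondyle_medial", "epicondyle_lateral"):
        setattr(lm, f, getattr(lm, f) * sf)
    model.subject_mass = float(subject_mass)
    model.subject_height = float(subject_height)
    model.fmax_scale = float(fmax_scale)
    model.meta = dict(model.meta)
    model.meta["scaled_from"] = {"mass": TEMPLATE_MASS,
                                 "height": TEMPLATE_HEIGHT}
    return model


def anatomical_fmax_sum() -> float:
    """Sum of the template's unscaled maximum isometric forces (N)."""
    d = _load_template_dict()
    return float(sum(m["params"]["f_max"] for m in d["muscles"]))
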