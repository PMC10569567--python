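"""Femoral anteversion (AVA) and neck-shaft angle (NSA): measurement,
proximal-femur deformation, and the factorial model sweep.

AVA is the transverse-plane angle by which the femoral neck deviates
anteriorly from the condylar (knee) axis; NSA is the angle between the neck
axis and the shaft axis.  Deformation rigidly rotates every femur-fixed
point in a proximal region (muscle attachments and landmarks) about the
shaft axis (for AVA) and about the normal of the neck-shaft plane through
the neck base (for NSA), leaving joint centers, segment masses and inertias
untouched -- which is what makes joint angles and net joint moments
identical across all models of a sweep.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError, ParameterError
from .geometry import angle_between, rotate_about_line, unit
from .model import (FemoralLandmarks, Model, Posture,
                    recalibrate_muscle_parameters, reference_posture)

#: proximal region extends this fraction of shaft length from the proximal end
DEFAULT_REGION_FRACTION = 0.4


@dataclass
class GeometryTarget:
    """Target femoral geometry in degrees."""

    ava: float
    nsa: float

    def __post_init__(self):
        if not -90.0 < self.ava < 90.0:
            raise ParameterError(f"ava {self.ava} outside (-90, 90) degrees")
        if not 90.0 < self.nsa < 180.0:
            raise ParameterError(f"nsa {self.nsa} outside (90, 180) degrees")


@dataclass
class SweepSpec:
    """Factorial sweep: reference geometry plus offsets applied to each of
    AVA and NSA (degrees)."""

    reference: GeometryTarget
    offsets: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    factorial: bool = True
    region_fraction: float = DEFAULT_REGION_FRACTION

    def __post_init__(self):
        if len(self.offsets) == 0:
            raise ParameterError("offsets must be non-empty")
        off = tuple(sorted(set(float(o) for o in self.offsets)))
        if off != tuple(float(o) for o in self.offsets):
            warnings.warn("offsets re-sorted / de-duplicated", stacklevel=2)
        self.offsets = off

    def targets(self) -> list[GeometryTarget]:
        avas = [self.reference.ava + o for o in self.offsets]
        nsas = [self.reference.nsa + o for o in self.offsets]
        if self.factorial:
            return [GeometryTarget(a, n)
                    for a, n in itertools.product(avas, nsas)]
        return [GeometryTarget(a, self.reference.nsa) for a in avas] + \
               [GeometryTarget(self.reference.ava, n) for n in nsas]


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _shaft_axes(lm: FemoralLandmarks):
    s_prox = unit(lm.shaft_proximal - lm.shaft_distal, "shaft axis")
    return s_prox


def measure_ava(landmarks: FemoralLandmarks) -> float:
    """Anteversion angle (degrees): signed angle between the neck axis and
    the condylar line, both projected onto the plane perpendicular to the
    shaft axis; positive anterior; range (-90, 90].

    The condylar axis is treated as a line (the knee axis), so the result
    measures the forward deviation of the neck from that line.  Anterior is
    ``shaft_proximal_dir x condylar_lateral_dir`` (right-leg convention).
    """
    s = _shaft_axes(landmarks)
    n = landmarks.head_center - landmarks.neck_base
    c = landmarks.epicondyle_lateral - landmarks.epicondyle_medial
    n_p = n - np.dot(n, s) * s
    c_p = c - np.dot(c, s) * s
    if np.linalg.norm(n_p) < 1e-12:
        raise DegenerateGeometryError("neck axis parallel to shaft axis")
    if np.linalg.norm(c_p) < 1e-12:
        raise DegenerateGeometryError("condylar axis parallel to shaft axis")
    c_hat = c_p / np.linalg.norm(c_p)
    anterior = unit(np.cross(s, c_hat), "anterior direction")
    return float(np.degrees(np.arctan2(np.dot(n_p, anterior),
                                       abs(np.dot(n_p, c_hat)))))


def measure_nsa(landmarks: FemoralLandmarks) -> float:
    """Neck-shaft angle (degrees): angle at the neck base between the neck
    axis (toward the head center) and the proximal-pointing shaft direction,
    reported in (0, 180)."""
    s = _shaft_axes(landmarks)
    n = landmarks.head_center - landmarks.neck_base
    return float(np.degrees(angle_between(n, s)))


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def _region_mask(points: np.ndarray, lm: FemoralLandmarks,
                 region_fraction: float) -> np.ndarray:
    """Boolean mask of points within the proximal deformation region."""
    d = lm.shaft_distal - lm.shaft_proximal
    length = np.linalg.norm(d)
    d_hat = d / length
    t = (points - lm.shaft_proximal) @ d_hat
    return t < region_fraction * length


def _rotation_sense(lm: FemoralLandmarks, axis: np.ndarray, origin: np.ndarray,
                    measure) -> float:
    """Sign of d(measure)/d(angle) for rotation of the in-region landmarks
    about the given line, by numeric probe."""
    eps = 1e-6
    probe = FemoralLandmarks(
        head_center=rotate_about_line(lm.head_center, axis, origin, eps),
        neck_base=rotate_about_line(lm.neck_base, axis, origin, eps),
        shaft_proximal=rotate_about_line(lm.shaft_proximal, axis, origin, eps),
        shaft_distal=lm.shaft_distal,
        epicondyle_medial=lm.epicondyle_medial,
        epicondyle_lateral=lm.epicondyle_lateral)
    return 1.0 if measure(probe) > measure(lm) else -1.0


def apply_deformation(model: Model, target: GeometryTarget,
                      region_fraction: float = DEFAULT_REGION_FRACTION) -> Model:
    """Deform the proximal femur to match the target AVA and NSA.

    Every femur-fixed point (muscle origins, insertions and via points, and
    the proximal landmarks) within the proximal region moves rigidly; the
    AVA rotation is applied about the shaft axis first, the NSA rotation
    about the neck-plane normal through the neck base second (finite
    rotations do not commute, so the order is fixed).  Joint locations,
    segment masses and inertias are untouched.
    """
    lm = model.landmarks
    if not _region_mask(lm.neck_base[None, :], lm, region_fraction)[0]:
        raise ConfigurationError(
            "proximal region boundary excludes the neck base")

    rotations: list[tuple[np.ndarray, np.ndarray, float]] = []

    def rotate_lm(lmk: FemoralLandmarks, axis, origin, angle) -> FemoralLandmarks:
        arr = lmk.as_array()
        mask = _region_mask(arr, lm, region_fraction)
        arr = np.where(mask[:, None],
                       rotate_about_line(arr, axis, origin, angle), arr)
        return FemoralLandmarks(*arr)

    # AVA: rotate about the shaft line
    current = lm
    s_axis = unit(lm.shaft_proximal - lm.shaft_distal)
    d_ava = np.deg2rad(target.ava - measure_ava(current))
    if abs(d_ava) > 1e-12:
        sense = _rotation_sense(current, s_axis, lm.shaft_proximal, measure_ava)
        angle = sense * d_ava
        rotations.append((s_axis, lm.shaft_proximal.copy(), angle))
        current = rotate_lm(current, s_axis, lm.shaft_proximal, angle)

    # NSA: rotate about the normal of the neck-shaft plane through neck_base
    d_nsa = np.deg2rad(target.nsa - measure_nsa(current))
    if abs(d_nsa) > 1e-12:
        n = current.head_center - current.neck_base
        normal = unit(np.cross(s_axis, n), "neck-shaft plane normal")
        sense = _rotation_sense(current, normal, current.neck_base, measure_nsa)
        angle = sense * d_nsa
        rotations.append((normal, current.neck_base.copy(), angle))
        current = rotate_lm(current, normal, current.neck_base, angle)

    out = model.copy()
    out.landmarks = current
    for m in out.muscles:
        new_points = []
        for seg, p in m.path.points:
            if seg == "femur" and _region_mask(p[None, :], lm,
                                               region_fraction)[0]:
                for axis, origin, angle in rotations:
                    p = rotate_about_line(p, axis, origin, angle)
            new_points.append((seg, p))
        m.path.points = new_points
    out.meta = dict(out.meta)
    out.meta["deformation"] = {
        "target_ava": target.ava, "target_nsa": target.nsa,
        "region_fraction": region_fraction}

    for name, measure, want in (("ava", measure_ava, target.ava),
                                ("nsa", measure_nsa, target.nsa)):
        got = measure(out.landmarks)
        if abs(got - want) > 0.1:
            raise ConfigurationError(
                f"deformation missed target {name}: {got:.3f} vs {want:.3f}")
    return out


def generate_sweep(model: Model, spec: SweepSpec,
                   recalibrate: bool = True) -> list[tuple[GeometryTarget, Model]]:
    """Full factorial sweep of deformed (and recalibrated) models.

    The reference geometry appears exactly once; duplicate targets collapse
    with a warning.  Each deformed model's optimal fiber and tendon slack
    lengths are rescaled so normalized fiber lengths at the anatomical
    reference posture match the reference model.
    """
    ref_post = reference_posture(model)
    seen: dict[tuple[float, float], bool] = {}
    out = []
    for t in spec.targets():
        key = (round(t.ava, 6), round(t.nsa, 6))
        if key in seen:
            warnings.warn(f"duplicate sweep target {key} collapsed",
                          stacklevel=2)
            continue
        seen[key] = True
        deformed = apply_deformation(model, t, spec.region_fraction)
        if recalibrate:
            deformed = recalibrate_muscle_parameters(deformed, ref_post, model)
        out.append((t, deformed))
    return out
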