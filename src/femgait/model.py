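"""Musculoskeletal model data structures and muscle-tendon geometry.

The model is a kinematic tree of rigid segments rooted at the pelvis, with
rotational degrees of freedom (DOFs) at the hip (3), knee (1) and ankle (1).
Muscles are straight-line paths through fixed via points; their lengths and
tendon-excursion moment arms (r = -dL/dq) follow from forward kinematics.
Muscle force follows a rigid-tendon Hill-type model: active force equals
activation x f_max x f_L(l) x f_V(v), where f_L is a Gaussian of normalized
fiber length and f_V a piecewise-hyperbolic function of normalized fiber
velocity.

Conventions: right-handed frames, X anterior, Y superior, Z right; angles in
degrees at public interfaces, radians internally; positive joint directions
are hip flexion, hip abduction, hip internal rotation, knee flexion, ankle
dorsiflexion.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, DegenerateGeometryError, FormatError, ParameterError
from .geometry import rotation_about_axis, unit

MODEL_SCHEMA_VERSION = "1.0"

#: finite-difference step for tendon-excursion moment arms (radians):
#: below the curvature scale of via-point geometry, above float noise.
MOMENT_ARM_STEP_RAD = 1e-4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A rigid body: mass (kg), center of mass (m, segment frame) and the
    inertia tensor about the COM (kg m^2, segment frame)."""

    name: str
    mass: float
    com: np.ndarray
    inertia: np.ndarray

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass <= 0:
            raise ParameterError(f"segment {self.name}: mass must be positive")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ParameterError(f"segment {self.name}: inertia must be symmetric")
        if np.min(np.linalg.eigvalsh(self.inertia)) < -1e-12:
            raise ParameterError(
                f"segment {self.name}: inertia must be positive semi-definite")


@dataclass
class DoF:
    """One rotational degree of freedom: unit axis in the parent frame and
    allowed range in degrees."""

    name: str
    axis: np.ndarray
    range_deg: tuple[float, float] = (-180.0, 180.0)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ParameterError(f"dof {self.name}: axis must have unit norm")


@dataclass
class Joint:
    name: str
    parent_segment: str
    child_segment: str
    location_in_parent: np.ndarray
    dofs: list[DoF]

    def __post_init__(self):
        self.location_in_parent = np.asarray(
            self.location_in_parent, dtype=float).reshape(3)


@dataclass
class MusclePath:
    """Ordered (segment, local point) pairs; first = origin, last = insertion."""

    points: list[tuple[str, np.ndarray]]

    def __post_init__(self):
        if len(self.points) < 2:
            raise ParameterError("muscle path needs at least 2 points")
        self.points = [(seg, np.asarray(p, dtype=float).reshape(3))
                       for seg, p in self.points]

    @property
    def segments(self) -> list[str]:
        return [seg for seg, _ in self.points]


@dataclass
class MuscleParams:
    """Hill-type scalars (rigid tendon).

    f_max N; l_opt, l_slack m; v_max in optimal fiber lengths / s; fl_width
    is the dimensionless Gaussian width of the active force-length curve;
    pennation in degrees (default 0).
    """

    f_max: float
    l_opt: float
    l_slack: float
    v_max: float = 10.0
    fl_width: float = 0.45
    pennation: float = 0.0

    def __post_init__(self):
        if min(self.f_max, self.l_opt, self.l_slack) <= 0:
            raise ParameterError("f_max, l_opt and l_slack must be positive")
        if self.v_max <= 0:
            raise ParameterError("v_max must be positive")
        if not 0.0 <= self.pennation < 90.0:
            raise ParameterError("pennation must be in [0, 90) degrees")


@dataclass
class Muscle:
    name: str
    path: MusclePath
    params: MuscleParams
    #: joints the muscle is considered to span, e.g. ("hip", "knee")
    spans: tuple[str, ...] = ()


@dataclass
class FemoralLandmarks:
    """Bony landmarks on the femur (femur frame, m) from which anteversion
    (AVA) and neck-shaft angle (NSA) are measured."""

    head_center: np.ndarray
    neck_base: np.ndarray
    shaft_proximal: np.ndarray
    shaft_distal: np.ndarray
    epicondyle_medial: np.ndarray
    epicondyle_lateral: np.ndarray

    def __post_init__(self):
        for f in ("head_center", "neck_base", "shaft_proximal", "shaft_distal",
                  "epicondyle_medial", "epicondyle_lateral"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=float).reshape(3))
        if np.linalg.norm(self.head_center - self.neck_base) < 1e-9:
            raise DegenerateGeometryError("head_center coincides with neck_base")
        if np.linalg.norm(self.shaft_proximal - self.shaft_distal) < 1e-9:
            raise DegenerateGeometryError("shaft axis is degenerate")
        if np.linalg.norm(self.epicondyle_lateral - self.epicondyle_medial) < 1e-9:
            raise DegenerateGeometryError("epicondyles coincide")

    def as_array(self) -> np.ndarray:
        return np.stack([self.head_center, self.neck_base, self.shaft_proximal,
                         self.shaft_distal, self.epicondyle_medial,
                         self.epicondyle_lateral])


@dataclass
class Model:
    """Single-leg lower-limb model: pelvis (base) -> femur -> tibia -> foot."""

    segments: dict[str, Segment]
    joints: list[Joint]
    muscles: list[Muscle]
    landmarks: FemoralLandmarks
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    subject_mass: float = 73.1
    subject_height: float = 1.71
    fmax_scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)
        self._validate_tree()
        names = {m.name for m in self.muscles}
        if len(names) != len(self.muscles):
            raise ParameterError("duplicate muscle names")
        for m in self.muscles:
            segs = m.path.segments
            for s in segs:
                if s not in self.segments:
                    raise ParameterError(
                        f"muscle {m.name}: unknown segment {s!r}")
            order = {s: i for i, s in enumerate(self.segment_order())}
            for a, b in zip(segs[:-1], segs[1:]):
                if abs(order[a] - order[b]) > 1:
                    raise ParameterError(
                        f"muscle {m.name}: consecutive path points must lie on "
                        f"the same or adjacent segments ({a} -> {b})")

    # -- structure ----------------------------------------------------------

    def _validate_tree(self):
        children = {}
        for j in self.joints:
            if j.parent_segment not in self.segments or \
                    j.child_segment not in self.segments:
                raise ParameterError(f"joint {j.name}: unknown segment")
            if j.child_segment in children.values():
                raise ParameterError("joint graph is not a tree")
            children[j.name] = j.child_segment
        roots = set(self.segments) - set(children.values())
        if roots != {"pelvis"}:
            raise ParameterError(
                f"joint graph must be a tree rooted at pelvis (roots: {roots})")

    def segment_order(self) -> list[str]:
        """Segments in root-to-leaf order."""
        order = ["pelvis"]
        for j in self.joints:
            order.append(j.child_segment)
        return order

    @property
    def dof_names(self) -> list[str]:
        return [d.name for j in self.joints for d in j.dofs]

    def dof_index(self, dof: str) -> int:
        try:
            return self.dof_names.index(dof)
        except ValueError:
            raise ParameterError(f"unknown dof {dof!r}") from None

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"unknown muscle {name!r}")

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def copy(self) -> "Model":
        return copy.deepcopy(self)


@dataclass
class Posture:
    """Mapping dof name -> angle (deg) and angular velocity (deg/s)."""

    angles: dict[str, float]
    velocities: dict[str, float] | None = None

    def q_vector(self, model: Model) -> np.ndarray:
        q = np.empty(len(model.dof_names))
        for i, (j, d) in enumerate(
                (j, d) for j in model.joints for d in j.dofs):
            if d.name not in self.angles:
                raise ParameterError(f"posture is missing dof {d.name!r}")
            a = self.angles[d.name]
            lo, hi = d.range_deg
            if not lo <= a <= hi:
                warnings.warn(
                    f"dof {d.name}: angle {a:.1f} deg outside range "
                    f"[{lo:.0f}, {hi:.0f}]", stacklevel=3)
            q[i] = a
        return q


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

class FKResult:
    """Batched forward-kinematics result over n frames.

    Attributes:
        R: dict segment -> (n, 3, 3) world orientation
        p: dict segment -> (n, 3) world frame-origin position
        joint_center: dict joint -> (n, 3)
        dof_axis_world: (n, ndof, 3) instantaneous world rotation axes
    """

    def __init__(self, R, p, joint_center, dof_axis_world):
        self.R = R
        self.p = p
        self.joint_center = joint_center
        self.dof_axis_world = dof_axis_world

    def point(self, segment: str, local: np.ndarray) -> np.ndarray:
        """World position (n, 3) of a point fixed in ``segment``."""
        local = np.asarray(local, dtype=float).reshape(3)
        return self.p[segment] + self.R[segment] @ local


def fk_batch(model: Model, q_deg: np.ndarray) -> FKResult:
    """Forward kinematics for a batch of postures.

    ``q_deg``: (n, ndof) joint angles in degrees, ordered as
    ``model.dof_names``.
    """
    q = np.deg2rad(np.atleast_2d(np.asarray(q_deg, dtype=float)))
    n, ndof = q.shape
    if ndof != len(model.dof_names):
        raise ParameterError(
            f"expected {len(model.dof_names)} dofs, got {ndof}")
    R = {"pelvis": np.broadcast_to(np.eye(3), (n, 3, 3)).copy()}
    p = {"pelvis": np.zeros((n, 3))}
    joint_center = {}
    axes = np.empty((n, ndof, 3))
    k = 0
    for j in model.joints:
        Rp, pp = R[j.parent_segment], p[j.parent_segment]
        o = pp + Rp @ j.location_in_parent
        joint_center[j.name] = o
        Rc = Rp
        for d in j.dofs:
            axes[:, k, :] = Rc @ d.axis
            Rc = Rc @ rotation_about_axis(d.axis, q[:, k])
            k += 1
        R[j.child_segment] = Rc
        p[j.child_segment] = o
    return FKResult(R, p, joint_center, axes)


def forward_kinematics(model: Model, posture: Posture) -> dict[str, np.ndarray]:
    """Global positions of every muscle path point and femoral landmark.

    Keys: ``"<muscle>[i]"`` for the i-th path point and ``"landmark:<name>"``
    for femoral landmarks.
    """
    fk = fk_batch(model, posture.q_vector(model)[None, :])
    out = {}
    for m in model.muscles:
        for i, (seg, local) in enumerate(m.path.points):
            out[f"{m.name}[{i}]"] = fk.point(seg, local)[0]
    for lm in ("head_center", "neck_base", "shaft_proximal", "shaft_distal",
               "epicondyle_medial", "epicondyle_lateral"):
        out[f"landmark:{lm}"] = fk.point("femur", getattr(model.landmarks, lm))[0]
    return out


# ---------------------------------------------------------------------------
# muscle-tendon geometry
# ---------------------------------------------------------------------------

def _path_world(fk: FKResult, muscle: Muscle) -> np.ndarray:
    """(npoints, n, 3) world positions of a muscle's path points."""
    return np.stack([fk.point(seg, local) for seg, local in muscle.path.points])


def mtu_lengths_batch(model: Model, q_deg: np.ndarray,
                      fk: FKResult | None = None) -> np.ndarray:
    """(n, nmuscles) muscle-tendon lengths for a batch of postures."""
    if fk is None:
        fk = fk_batch(model, q_deg)
    out = np.empty((fk.dof_axis_world.shape[0], len(model.muscles)))
    for i, m in enumerate(model.muscles):
        pts = _path_world(fk, m)
        out[:, i] = np.linalg.norm(np.diff(pts, axis=0), axis=2).sum(axis=0)
    return out


def mtu_length(model: Model, posture: Posture, muscle: str) -> float:
    """Muscle-tendon length (m): sum of straight-line distances between
    consecutive global path points."""
    m = model.muscle(muscle)
    fk = fk_batch(model, posture.q_vector(model)[None, :])
    pts = _path_world(fk, m)[:, 0, :]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def moment_arms_batch(model: Model, q_deg: np.ndarray,
                      step_rad: float = MOMENT_ARM_STEP_RAD) -> np.ndarray:
    """Tendon-excursion moment arms r = -dL/dq for all muscles and dofs.

    Returns (n, nmuscles, ndof) in meters; q in radians internally so the
    arm is in m per radian, i.e. meters.
    """
    q = np.atleast_2d(np.asarray(q_deg, dtype=float))
    n, ndof = q.shape
    h_deg = np.rad2deg(step_rad)
    out = np.empty((n, len(model.muscles), ndof))
    for k in range(ndof):
        qp, qm = q.copy(), q.copy()
        qp[:, k] += h_deg
        qm[:, k] -= h_deg
        Lp = mtu_lengths_batch(model, qp)
        Lm = mtu_lengths_batch(model, qm)
        out[:, :, k] = -(Lp - Lm) / (2.0 * step_rad)
    return out


def moment_arm(model: Model, posture: Posture, muscle: str, dof: str,
               step_rad: float = MOMENT_ARM_STEP_RAD) -> float:
    """Moment arm (m) of ``muscle`` about ``dof`` by central finite
    difference of MTU length; positive arm means muscle tension produces a
    positive moment about the dof.

    Near the dof's range limits the stencil is clamped inside the range
    (with a warning) rather than stepping outside it.
    """
    mi = model.muscle_names.index(model.muscle(muscle).name)
    k = model.dof_index(dof)
    q = posture.q_vector(model)
    d = [d for j in model.joints for d in j.dofs][k]
    lo, hi = d.range_deg
    h_deg = np.rad2deg(step_rad)
    a_p, a_m = q[k] + h_deg, q[k] - h_deg
    if a_p > hi or a_m < lo:
        warnings.warn(f"dof {dof}: finite-difference stencil clamped at range "
                      "limit", stacklevel=2)
        a_p, a_m = min(a_p, hi), max(a_m, lo)
        if a_p - a_m < 1e-9:
            raise ParameterError(f"dof {dof}: range too narrow for stencil")
    qp, qm = q.copy(), q.copy()
    qp[k], qm[k] = a_p, a_m
    Lp = mtu_lengths_batch(model, qp[None, :])[0, mi]
    Lm = mtu_lengths_batch(model, qm[None, :])[0, mi]
    return float(-(Lp - Lm) / np.deg2rad(a_p - a_m))


# ---------------------------------------------------------------------------
# Hill-type force scalars (rigid tendon)
# ---------------------------------------------------------------------------

#: concentric force-velocity curvature (Hill constant a/F0)
_FV_K_CON = 0.25
#: eccentric plateau and curvature chosen for C1 continuity at v = 0:
#: slope of the concentric branch at 0 is 1 + 1/k = 5, so k_ecc = 0.4/5.
_FV_MAX_ECC = 1.4
_FV_K_ECC = (_FV_MAX_ECC - 1.0) / (1.0 + 1.0 / _FV_K_CON)


def force_length(l_norm, fl_width: float = 0.45):
    """Active force-length scalar: Gaussian exp(-((l-1)/w)^2).

    Negative fiber lengths give 0 with a warning (slack fiber)."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm < 0):
        warnings.warn("negative normalized fiber length; force-length set to 0",
                      stacklevel=2)
    fl = np.exp(-(((l_norm - 1.0) / fl_width) ** 2))
    return np.where(l_norm < 0, 0.0, fl)


def force_velocity(v_norm):
    """Force-velocity scalar of normalized fiber velocity v/v_max
    (shortening negative): hyperbolic concentric branch with f_V(0) = 1 and
    f_V(-1) = 0, eccentric branch saturating at 1.4, C1-continuous at 0."""
    v = np.asarray(v_norm, dtype=float)
    con = np.clip((1.0 + v) / (1.0 - v / _FV_K_CON), 0.0, None)
    ecc = (_FV_MAX_ECC * v + _FV_K_ECC) / (v + _FV_K_ECC)
    return np.where(v < 0, con, ecc)


def force_scalars(norm_fiber_length, norm_fiber_velocity,
                  fl_width: float = 0.45):
    """(f_L, f_V) for normalized fiber length and velocity."""
    return (force_length(norm_fiber_length, fl_width),
            force_velocity(norm_fiber_velocity))


def fiber_state(params: MuscleParams, mtu_len, mtu_vel):
    """Rigid-tendon fiber kinematics: normalized fiber length and velocity
    from MTU length (m) and lengthening velocity (m/s)."""
    cosp = np.cos(np.deg2rad(params.pennation))
    l_fiber = (np.asarray(mtu_len, dtype=float) - params.l_slack) / cosp
    l_norm = l_fiber / params.l_opt
    v_norm = (np.asarray(mtu_vel, dtype=float) / cosp) / (
        params.l_opt * params.v_max)
    return l_norm, v_norm


# ---------------------------------------------------------------------------
# recalibration after scaling / deformation
# ---------------------------------------------------------------------------

def recalibrate_muscle_parameters(model: Model, reference_posture: Posture,
                                  reference_model: Model) -> Model:
    """Rescale each muscle's optimal fiber and tendon slack lengths by the
    ratio of its MTU length (at the reference posture) in ``model`` versus
    ``reference_model``, so the normalized fiber length at the reference
    posture is preserved across deformed models."""
    if set(model.muscle_names) != set(reference_model.muscle_names):
        raise ParameterError("models do not share muscle names")
    q = reference_posture.q_vector(model)[None, :]
    L_new = mtu_lengths_batch(model, q)[0]
    L_ref = mtu_lengths_batch(
        reference_model, reference_posture.q_vector(reference_model)[None, :])[0]
    ref_idx = {n: i for i, n in enumerate(reference_model.muscle_names)}
    out = model.copy()
    for i, m in enumerate(out.muscles):
        lr = L_ref[ref_idx[m.name]]
        if lr < 1e-9:
            raise DataError(f"muscle {m.name}: zero reference MTU length")
        factor = L_new[i] / lr
        m.params.l_opt *= factor
        m.params.l_slack *= factor
    return out


# ---------------------------------------------------------------------------
# JSON serialization (schema version 1.0)
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "meta": dict(model.meta),
        "subject": {"mass": model.subject_mass, "height": model.subject_height,
                    "fmax_scale": model.fmax_scale},
        "gravity": model.gravity.tolist(),
        "segments": [
            {"name": s.name, "mass": s.mass, "com": s.com.tolist(),
             "inertia": s.inertia.tolist()}
            for s in model.segments.values()],
        "joints": [
            {"name": j.name, "parent": j.parent_segment,
             "child": j.child_segment,
             "location_in_parent": j.location_in_parent.tolist(),
             "dofs": [{"name": d.name, "axis": d.axis.tolist(),
                       "range": list(d.range_deg)} for d in j.dofs]}
            for j in model.joints],
        "muscles": [
            {"name": m.name,
             "path": [{"segment": seg, "point": p.tolist()}
                      for seg, p in m.path.points],
             "params": {"f_max": m.params.f_max, "l_opt": m.params.l_opt,
                        "l_slack": m.params.l_slack, "v_max": m.params.v_max,
                        "fl_width": m.params.fl_width,
                        "pennation": m.params.pennation},
             "spans": list(m.spans)}
            for m in model.muscles],
        "landmarks": {k: getattr(model.landmarks, k).tolist()
                      for k in ("head_center", "neck_base", "shaft_proximal",
                                "shaft_distal", "epicondyle_medial",
                                "epicondyle_lateral")},
    }


def model_from_dict(d: dict) -> Model:
    version = d.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})")
    try:
        segments = {s["name"]: Segment(s["name"], s["mass"],
                                       np.array(s["com"]),
                                       np.array(s["inertia"]))
                    for s in d["segments"]}
        joints = [Joint(j["name"], j["parent"], j["child"],
                        np.array(j["location_in_parent"]),
                        [DoF(x["name"], np.array(x["axis"]),
                             tuple(x.get("range", (-180.0, 180.0))))
                         for x in j["dofs"]])
                  for j in d["joints"]]
        muscles = [Muscle(m["name"],
                          MusclePath([(p["segment"], np.array(p["point"]))
                                      for p in m["path"]]),
                          MuscleParams(**m["params"]),
                          tuple(m.get("spans", ())))
                   for m in d["muscles"]]
        landmarks = FemoralLandmarks(**{k: np.array(v)
                                        for k, v in d["landmarks"].items()})
        subject = d.get("subject", {})
    except (KeyError, TypeError) as e:
        raise FormatError(f"malformed model description: {e}") from e
    return Model(segments=segments, joints=joints, muscles=muscles,
                 landmarks=landmarks,
                 gravity=np.array(d.get("gravity", [0.0, -9.81, 0.0])),
                 subject_mass=subject.get("mass", 73.1),
                 subject_height=subject.get("height", 1.71),
                 fmax_scale=subject.get("fmax_scale", 1.0),
                 meta=d.get("meta", {}))


def save_model(model: Model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> Model:
    return model_from_dict(json.loads(Path(path).read_text()))


def reference_posture(model: Model) -> Posture:
    """Anatomical zero posture (all dof angles and velocities zero)."""
    return Posture({d: 0.0 for d in model.dof_names},
                   {d: 0.0 for d in model.dof_names})
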