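"""Inverse dynamics and joint-reaction (contact force) analysis.

Inverse dynamics runs a recursive Newton-Euler pass from the foot to the
pelvis with the ground reaction force applied at the center of pressure:
it yields the net moment about each degree of freedom (the generalized
force conjugate to that joint angle) and the intersegmental force at each
joint, expressed in the ground frame.  Segment velocities and accelerations
come from central finite differences of the forward-kinematics trajectories
(one-sided at the endpoints, via ``np.gradient``).

Joint-reaction analysis repeats the force balance with the muscle tensions
applied explicitly along their line of action at each attachment point;
the force transmitted through the articular surface (parent on child) is
the joint contact force.  With all muscle forces zero it reduces exactly to
the intersegmental force from inverse dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .gait import GaitTrial
from .model import FKResult, Model, fk_batch

GRAVITY_BW = 9.81


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class JointKinetics:
    """Per-frame net joint moments (N m) per dof and intersegmental forces
    (N, ground frame) per joint, plus cached kinematic quantities reused by
    the muscle-force stages."""

    time: np.ndarray
    q_deg: np.ndarray                    # (n, ndof)
    moments: np.ndarray                  # (n, ndof)
    forces: dict[str, np.ndarray]        # joint -> (n, 3)
    joint_moment_vectors: dict[str, np.ndarray]  # joint -> (n, 3)
    fk: FKResult
    com_acc: dict[str, np.ndarray]       # segment -> (n, 3)

    @property
    def n_frames(self) -> int:
        return len(self.time)


@dataclass
class JointContactForces:
    """Per-frame joint contact force vectors (N, ground frame), their
    resultant magnitudes, and the resultant in body weights."""

    time: np.ndarray
    vectors: dict[str, np.ndarray]       # joint -> (n, 3)
    magnitude: dict[str, np.ndarray]     # joint -> (n,)
    magnitude_bw: dict[str, np.ndarray]  # joint -> (n,)


# ---------------------------------------------------------------------------
# kinematic derivatives
# ---------------------------------------------------------------------------

def _angular_velocity(R: np.ndarray, t: np.ndarray):
    """Angular velocity and acceleration (ground frame) from a stack of
    rotation matrices via skew(omega) = dR/dt R^T."""
    dR = np.gradient(R, t, axis=0)
    W = dR @ np.transpose(R, (0, 2, 1))
    omega = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)
    alpha = np.gradient(omega, t, axis=0)
    return omega, alpha


def trial_q(model: Model, trial: GaitTrial) -> np.ndarray:
    """(n, ndof) joint-angle matrix in model dof order."""
    missing = [d for d in model.dof_names if d not in trial.angles]
    if missing:
        raise ParameterError(f"trial is missing dofs: {missing}")
    return np.column_stack([trial.angles[d] for d in model.dof_names])


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

def inverse_dynamics(model: Model, trial: GaitTrial) -> JointKinetics:
    """Recursive Newton-Euler inverse dynamics over a trial.

    Returns net moments about each dof axis (instantaneous world axis of
    the corresponding rotation) and the intersegmental force each parent
    exerts on its child, in the ground frame.
    """
    q = trial_q(model, trial)
    t = trial.time
    n = len(t)
    fk = fk_batch(model, q)
    g = model.gravity

    com_w, acc, omega, alpha, inertia_w = {}, {}, {}, {}, {}
    for name, seg in model.segments.items():
        R, p = fk.R[name], fk.p[name]
        c = p + R @ seg.com
        com_w[name] = c
        acc[name] = np.gradient(np.gradient(c, t, axis=0), t, axis=0)
        w, a = _angular_velocity(R, t)
        omega[name], alpha[name] = w, a
        inertia_w[name] = R @ seg.inertia @ np.transpose(R, (0, 2, 1))

    # external load: GRF on the foot at the COP
    ext_force = {name: np.zeros((n, 3)) for name in model.segments}
    ext_point = {name: np.zeros((n, 3)) for name in model.segments}
    ext_force["foot"] = trial.grf
    ext_point["foot"] = trial.cop

    child_joint = {}  # parent segment -> list of joints where it is parent
    for j in model.joints:
        child_joint.setdefault(j.parent_segment, []).append(j)

    forces: dict[str, np.ndarray] = {}
    moment_vec: dict[str, np.ndarray] = {}
    for j in reversed(model.joints):
        s = j.child_segment
        seg = model.segments[s]
        c = com_w[s]
        F = seg.mass * acc[s] - seg.mass * g - ext_force[s]
        Iw = inertia_w[s]
        Iw_w = np.einsum("nij,nj->ni", Iw, omega[s])
        M = (np.einsum("nij,nj->ni", Iw, alpha[s])
             + np.cross(omega[s], Iw_w))
        M -= np.cross(ext_point[s] - c, ext_force[s])
        for jc in child_joint.get(s, []):
            F += forces[jc.name]
            M += moment_vec[jc.name]
            M += np.cross(fk.joint_center[jc.name] - c, forces[jc.name])
        o = fk.joint_center[j.name]
        M -= np.cross(o - c, F)
        forces[j.name] = F
        moment_vec[j.name] = M

    # project joint moment vectors onto instantaneous dof axes
    moments = np.empty((n, len(model.dof_names)))
    k = 0
    for j in model.joints:
        for _ in j.dofs:
            moments[:, k] = np.einsum(
                "ni,ni->n", moment_vec[j.name], fk.dof_axis_world[:, k, :])
            k += 1

    return JointKinetics(time=t, q_deg=q, moments=moments, forces=forces,
                         joint_moment_vectors=moment_vec, fk=fk, com_acc=acc)


# ---------------------------------------------------------------------------
# muscle forces on segments
# ---------------------------------------------------------------------------

def muscle_segment_forces(model: Model, fk: FKResult,
                          tensions: np.ndarray) -> dict[str, np.ndarray]:
    """Net force (n, 3) each segment receives from all muscle tensions.

    A path segment between consecutive points pulls the two endpoints
    toward each other with the muscle's tension; each attachment point
    transmits the sum of the unit vectors toward its path neighbors times
    the tension to the segment it sits on.
    """
    n = tensions.shape[0]
    out = {name: np.zeros((n, 3)) for name in model.segments}
    for i, m in enumerate(model.muscles):
        pts = np.stack([fk.point(seg, p) for seg, p in m.path.points])
        d = np.diff(pts, axis=0)
        u = d / np.linalg.norm(d, axis=2, keepdims=True)
        T = tensions[:, i][None, :, None]
        for k, (seg, _) in enumerate(m.path.points):
            f = np.zeros((n, 3))
            if k < len(m.path.points) - 1:
                f = f + u[k] * T[0]
            if k > 0:
                f = f - u[k - 1] * T[0]
            out[seg] += f
    return out


# ---------------------------------------------------------------------------
# joint reaction analysis
# ---------------------------------------------------------------------------

def joint_reaction_analysis(model: Model, trial: GaitTrial, solution,
                            kinetics: JointKinetics) -> JointContactForces:
    """Joint contact forces: the force the parent exerts on the child
    through the articular surface once muscle tensions act explicitly.

    ``solution`` may be a MuscleSolution or any object with a ``forces``
    array of shape (n_frames, n_muscles); frame counts must align.
    """
    tensions = np.asarray(solution.forces, dtype=float)
    n = kinetics.n_frames
    if tensions.shape != (n, len(model.muscles)):
        raise ParameterError(
            f"muscle-force array {tensions.shape} does not align with "
            f"{n} frames x {len(model.muscles)} muscles")
    fk = kinetics.fk
    g = model.gravity
    musc = muscle_segment_forces(model, fk, tensions)

    ext_force = {name: np.zeros((n, 3)) for name in model.segments}
    ext_force["foot"] = trial.grf

    child_joint = {}
    for j in model.joints:
        child_joint.setdefault(j.parent_segment, []).append(j)

    vectors: dict[str, np.ndarray] = {}
    for j in reversed(model.joints):
        s = j.child_segment
        seg = model.segments[s]
        F = (seg.mass * kinetics.com_acc[s] - seg.mass * g
             - ext_force[s] - musc[s])
        for jc in child_joint.get(s, []):
            F += vectors[jc.name]
        vectors[j.name] = F

    bw = model.subject_mass * GRAVITY_BW
    magnitude = {k: np.linalg.norm(v, axis=1) for k, v in vectors.items()}
    return JointContactForces(
        time=kinetics.time, vectors=vectors, magnitude=magnitude,
        magnitude_bw={k: v / bw for k, v in magnitude.items()})
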