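"""Static-optimization muscle-force estimation.

Per frame, activations minimize the sum of squared activations subject to
moment equilibrium about every degree of freedom and activation bounds
[0, 1]:

    min sum_i a_i^2
    s.t. sum_i a_i * g_i * r_ij = tau_j   for every dof j
         0 <= a_i <= 1

where g_i = f_max_i * f_L * f_V is the muscle's active force per unit
activation under the rigid-tendon model (so the problem is a convex QP)
and r_ij is the tendon-excursion moment arm.  Muscle tension is
F_i = a_i * g_i.

Frames whose required moments exceed muscle capacity are flagged, not
fatal: the solver then reports the minimum-norm constraint violation.
A grid-enumeration oracle for tiny (<= 3 muscles, single-dof) problems
provides an independent check of the QP path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ParameterError, SolverError
from .dynamics import JointKinetics, trial_q
from .gait import GaitTrial
from .model import Model, fiber_state, force_scalars, moment_arms_batch, \
    mtu_lengths_batch

#: equilibrium residual (N m) below which a frame counts as converged
RESIDUAL_TOL = 1e-6


@dataclass
class MuscleSolution:
    """Activations (n, nm) in [0, 1], muscle tensions (n, nm) in N, the
    per-frame activation-to-force gains, equilibrium residuals (N m,
    infinity norm) and convergence flags."""

    time: np.ndarray
    muscle_names: list[str]
    activations: np.ndarray
    forces: np.ndarray
    gains: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    moment_arms: np.ndarray   # (n, nm, ndof), cached for moment analysis

    @property
    def n_frames(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# single-frame QP
# ---------------------------------------------------------------------------

def _min_norm_eq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum-norm solution of A x = b (least squares if inconsistent)."""
    return np.linalg.lstsq(A, b, rcond=None)[0]


def _polish_active_set(A, b, x, tol=1e-9):
    """Re-solve the equality-constrained minimum-norm problem on the free
    variables with bound-active variables clamped, to drive the residual to
    machine precision after an iterative solve."""
    x = np.clip(x, 0.0, 1.0)
    for _ in range(3):
        lower = x <= 1e-7
        upper = x >= 1.0 - 1e-7
        free = ~(lower | upper)
        if not np.any(free):
            break
        b_eff = b - A[:, upper] @ np.ones(upper.sum())
        xf = _min_norm_eq(A[:, free], b_eff)
        cand = np.where(lower, 0.0, np.where(upper, 1.0, 0.0))
        cand[free] = xf
        if np.all((cand > -tol) & (cand < 1.0 + tol)):
            x = np.clip(cand, 0.0, 1.0)
        else:
            break
    return x


def solve_frame_qp(A: np.ndarray, b: np.ndarray,
                   tol: float = RESIDUAL_TOL):
    """Solve one static-optimization frame.

    A: (ndof, nm) constraint matrix with entries g_i * r_ij; b: (ndof,)
    net joint moments.  Returns (activations, residual_inf, converged).
    """
    nm = A.shape[1]
    x = _min_norm_eq(A, b)
    if np.all((x >= 0.0) & (x <= 1.0)):
        res = np.max(np.abs(A @ x - b)) if A.size else 0.0
        if res < tol:
            return x, res, True
    x0 = np.clip(x, 0.0, 1.0)
    result = optimize.minimize(
        lambda a: a @ a, x0, jac=lambda a: 2.0 * a,
        bounds=[(0.0, 1.0)] * nm,
        constraints=[{"type": "eq", "fun": lambda a: A @ a - b,
                      "jac": lambda a: A}],
        method="SLSQP", options={"maxiter": 300, "ftol": 1e-12})
    x = _polish_active_set(A, b, result.x)
    res = float(np.max(np.abs(A @ x - b)))
    if res < tol:
        return x, res, True
    # infeasible frame: minimum constraint violation within bounds
    lsq = optimize.lsq_linear(A, b, bounds=(0.0, 1.0), tol=1e-12)
    x = lsq.x
    res = float(np.max(np.abs(A @ x - b)))
    return np.clip(x, 0.0, 1.0), res, False


# ---------------------------------------------------------------------------
# whole-trial solve
# ---------------------------------------------------------------------------

def muscle_gains(model: Model, q_deg: np.ndarray,
                 time: np.ndarray) -> np.ndarray:
    """(n, nm) activation-to-force gains f_max * f_L * f_V along a
    trajectory, using rigid-tendon fiber kinematics and finite-difference
    MTU velocities."""
    L = mtu_lengths_batch(model, q_deg)
    V = np.gradient(L, time, axis=0)
    gains = np.empty_like(L)
    for i, m in enumerate(model.muscles):
        l_norm, v_norm = fiber_state(m.params, L[:, i], V[:, i])
        f_l, f_v = force_scalars(l_norm, v_norm, m.params.fl_width)
        gains[:, i] = m.params.f_max * f_l * f_v
    return np.clip(gains, 0.0, None)


def solve_static_optimization(model: Model, trial: GaitTrial,
                              kinetics: JointKinetics,
                              tol: float = RESIDUAL_TOL) -> MuscleSolution:
    """Frame-by-frame static optimization over a trial."""
    q = trial_q(model, trial)
    n = q.shape[0]
    if kinetics.n_frames != n:
        raise ParameterError("kinetics frames do not align with the trial")
    gains = muscle_gains(model, q, trial.time)
    arms = moment_arms_batch(model, q)          # (n, nm, ndof)
    nm = len(model.muscles)
    activations = np.zeros((n, nm))
    residual = np.zeros(n)
    converged = np.zeros(n, dtype=bool)
    for f in range(n):
        A = (arms[f] * gains[f][:, None]).T     # (ndof, nm)
        try:
            a, res, ok = solve_frame_qp(A, kinetics.moments[f], tol)
        except Exception as e:  # pragma: no cover - defensive
            raise SolverError(str(e), frame=f) from e
        activations[f] = a
        residual[f] = res
        converged[f] = ok
    forces = activations * gains
    return MuscleSolution(time=trial.time, muscle_names=model.muscle_names,
                          activations=activations, forces=forces,
                          gains=gains, residual=residual,
                          converged=converged, moment_arms=arms)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_oracle(gains, moment_arms, tau: float,
                       grid_step: float = 0.001) -> np.ndarray:
    """Exhaustive-grid solution of the single-dof redundancy problem.

    Enumerates the activation grid {0, step, ..., 1}^(n-1) over all but
    one muscle and, for each grid point, enforces equilibrium exactly by
    eliminating the muscle with the strongest moment contribution; the
    minimizer of sum a_i^2 over all feasible completions is returned.
    Solving one coordinate exactly (rather than allowing an equilibrium
    tolerance) keeps the search from trading constraint slack for
    objective, so the oracle converges to the continuum optimum at rate
    O(step).  Restricted to <= 3 muscles to keep the enumeration
    tractable.
    """
    g = np.asarray(gains, dtype=float)
    r = np.asarray(moment_arms, dtype=float)
    if g.shape != r.shape or g.ndim != 1:
        raise ParameterError("gains and moment_arms must be equal-length 1-D")
    nmusc = len(g)
    if nmusc > 3:
        raise ParameterError("oracle refuses more than 3 muscles")
    if nmusc == 0:
        raise ParameterError("need at least one muscle")
    c = g * r
    if np.max(np.abs(c)) < 1e-15:
        if abs(tau) > 1e-12:
            raise SolverError("zero gains cannot balance a nonzero moment")
        return np.zeros(nmusc)
    # solve the coordinate with the largest |gain x arm| from the rest
    pivot = int(np.argmax(np.abs(c)))
    order = [i for i in range(nmusc) if i != pivot] + [pivot]
    c_ord = c[order]
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)

    if nmusc == 1:
        heads = np.zeros((1, 0))
        partial = np.zeros(1)
    else:
        mesh = np.meshgrid(*([grid] * (nmusc - 1)), indexing="ij")
        heads = np.stack([m.ravel() for m in mesh], axis=1)
        partial = heads @ c_ord[:-1]
    exact = (tau - partial) / c_ord[-1]
    feas = (exact >= -1e-12) & (exact <= 1.0 + 1e-12)
    if not np.any(feas):
        raise SolverError("oracle found no feasible grid point")
    cand = heads[feas]
    last = np.clip(exact[feas], 0.0, 1.0)
    obj = (cand ** 2).sum(axis=1) + last ** 2
    k = int(np.argmin(obj))
    a_ord = np.append(cand[k], last[k])
    out = np.empty(nmusc)
    out[order] = a_ord
    return out
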