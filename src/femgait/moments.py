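"""Muscle moments, functional grouping, and the co-contraction index (CCI).

The moment a muscle generates in an anatomical plane is its tension times
its moment arm about the corresponding degree of freedom, per frame.
Positive directions are fixed by plane naming: hip flexion, hip abduction,
hip internal rotation and knee flexion are positive, so the positive-
direction sum is the "agonist" moment and the magnitude of the negative-
direction sum the "antagonist" moment.  The CCI maps the two sums onto
[-1, 1]:

    CCI = 1 - M_agonist / M_antagonist      if M_antagonist > M_agonist
    CCI = M_antagonist / M_agonist - 1      otherwise

so 0 means full co-contraction, 1 antagonist-only and -1 agonist-only
activity.  When both sums are zero the index is undefined and propagates
as NaN (excluded from stance means with a reported count): zero has to
mean "full co-contraction", not "no contraction".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import Model
from .staticopt import MuscleSolution

#: anatomical planes analyzed (dof names; ankle is not analyzed)
PLANES = ("hip_flexion", "hip_abduction", "hip_rotation", "knee_flexion")

#: |moment arm| below this (m) counts as no action in the plane
NEUTRAL_ARM_THRESHOLD = 1e-4


@dataclass
class MuscleMomentTable:
    """Per-frame, per-muscle, per-plane moments (N m, or N m/kg when
    normalized by body mass)."""

    time: np.ndarray
    muscle_names: list[str]
    planes: tuple[str, ...]
    values: np.ndarray          # (n, nm, nplanes)
    per_mass: bool = False


@dataclass
class GroupedMoments:
    """Per-frame positive-direction (agonist) and negative-direction
    (antagonist) moment sums per plane, both reported as magnitudes."""

    time: np.ndarray
    planes: tuple[str, ...]
    agonist: np.ndarray         # (n, nplanes), >= 0
    antagonist: np.ndarray      # (n, nplanes), >= 0


@dataclass
class CCISeries:
    """Per-frame co-contraction index per plane, NaN where undefined."""

    time: np.ndarray
    planes: tuple[str, ...]
    values: np.ndarray          # (n, nplanes) in [-1, 1] or NaN


def compute_muscle_moments(model: Model, solution: MuscleSolution,
                           normalize_by_mass: bool = False,
                           planes: tuple[str, ...] = PLANES) -> MuscleMomentTable:
    """Muscle moments: tension x moment arm, per plane and frame."""
    idx = [model.dof_index(p) for p in planes]
    arms = solution.moment_arms[:, :, idx]
    if solution.forces.shape[:2] != arms.shape[:2]:
        raise ParameterError("solution forces and moment arms misaligned")
    values = solution.forces[:, :, None] * arms
    if normalize_by_mass:
        values = values / model.subject_mass
    return MuscleMomentTable(time=solution.time,
                             muscle_names=list(solution.muscle_names),
                             planes=planes, values=values,
                             per_mass=normalize_by_mass)


def classify_function(moment_arm_series, mode: str = "per_frame",
                      stance_fraction: float | None = None,
                      threshold: float = NEUTRAL_ARM_THRESHOLD):
    """Functional role of a muscle in a plane from its moment-arm series.

    ``per_frame``: one label per frame from the sign of the frame's arm.
    ``stance_mean``: a single label from the sign of the stance-phase mean
    arm (requires ``stance_fraction`` and a 101-sample cycle-normalized
    series).  Arms below ``threshold`` in magnitude are ``neutral``.
    """
    arms = np.asarray(moment_arm_series, dtype=float)
    if arms.size == 0:
        raise ParameterError("empty moment-arm series")

    def label(x):
        if abs(x) < threshold:
            return "neutral"
        return "agonist" if x > 0 else "antagonist"

    if mode == "per_frame":
        return np.array([label(x) for x in arms])
    if mode == "stance_mean":
        if stance_fraction is None:
            raise ParameterError("stance_mean mode needs stance_fraction")
        n_stance = int(round(stance_fraction * (len(arms) - 1))) + 1
        return label(float(np.mean(arms[:n_stance])))
    raise ParameterError(f"unknown mode {mode!r}")


def group_moments(table: MuscleMomentTable) -> GroupedMoments:
    """Positive- and negative-direction moment sums per plane and frame."""
    v = table.values
    agonist = np.clip(v, 0.0, None).sum(axis=1)
    antagonist = np.abs(np.clip(v, None, 0.0).sum(axis=1))
    return GroupedMoments(time=table.time, planes=table.planes,
                          agonist=agonist, antagonist=antagonist)


def compute_cci(m_agonist, m_antagonist):
    """Co-contraction index of agonist/antagonist moment sums.

    Accepts scalars or arrays; negative inputs raise; both-zero is NaN.
    """
    ag = np.asarray(m_agonist, dtype=float)
    an = np.asarray(m_antagonist, dtype=float)
    if np.any(ag < 0) or np.any(an < 0):
        raise ParameterError("moment sums must be non-negative")
    scalar = ag.ndim == 0 and an.ndim == 0
    ag, an = np.broadcast_arrays(np.atleast_1d(ag), np.atleast_1d(an))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ant_dom = an > ag
        out = np.where(ant_dom, 1.0 - ag / an, an / ag - 1.0)
    out = np.where((ag == 0) & (an == 0), np.nan, out)
    return float(out.item()) if scalar else out


def cci_series(grouped: GroupedMoments) -> CCISeries:
    """Per-frame CCI per plane from grouped moments."""
    return CCISeries(time=grouped.time, planes=grouped.planes,
                     values=compute_cci(grouped.agonist, grouped.antagonist))


def stance_mean(series, stance_fraction: float):
    """Mean of a 101-sample cycle-normalized series over stance samples
    0 .. round(stance_fraction * 100) inclusive, excluding NaNs.

    Returns (mean, n_excluded); an all-missing stance window returns
    (nan, count).
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] != 101:
        raise ParameterError("expected a 101-sample cycle-normalized series")
    if not 0.0 < stance_fraction < 1.0:
        raise ParameterError("stance_fraction must be in (0, 1)")
    window = x[:int(round(stance_fraction * 100)) + 1]
    missing = np.isnan(window)
    n_excluded = int(missing.sum())
    if n_excluded == len(window):
        return float("nan"), n_excluded
    return float(np.mean(window[~missing])), n_excluded
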