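"""The full femoral-geometry what-if study.

One synthetic gait trial is shared by every model of the factorial
anteversion x neck-shaft-angle sweep (the deformation leaves segment
dimensions and joints untouched, so joint angles and net joint moments are
identical across models by construction).  Per model the pipeline runs
deform -> recalibrate -> inverse dynamics -> static optimization -> joint
reaction analysis -> moment / co-contraction analysis -> stance-phase
summary, and a multiple regression then predicts each stance-mean outcome
from (AVA, NSA).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import (JointKinetics, inverse_dynamics,
                       joint_reaction_analysis)
from .errors import ConfigurationError, ParameterError
from .gait import (DEFAULT_CADENCE, DEFAULT_STANCE_FRACTION, GaitTrial,
                   normalize_to_cycle, synthesize_trial)
from .model import Model
from .moments import (PLANES, cci_series, classify_function,
                      compute_muscle_moments, group_moments, stance_mean)
from .motionio import write_motion
from .regression import RegressionResult, fit_ols
from .staticopt import solve_static_optimization
from .template import build_template_model
from .torsion import GeometryTarget, SweepSpec, generate_sweep

logger = logging.getLogger("femgait.study")

#: direction labels per plane: (positive direction, negative direction)
PLANE_DIRECTIONS = {
    "hip_flexion": ("hip_flexor", "hip_extensor"),
    "hip_abduction": ("hip_abductor", "hip_adductor"),
    "hip_rotation": ("hip_int_rot", "hip_ext_rot"),
    "knee_flexion": ("knee_flexor", "knee_extensor"),
}

_CONFIG_FIELDS = {
    "subject_mass", "subject_height", "walking_velocity", "fmax_scale",
    "sweep_offsets", "stance_fraction", "cadence", "noise_sd", "seed",
    "region_fraction", "solver_tol", "out_dir",
}


@dataclass
class StudyConfig:
    """Study parameters; defaults are the reference-subject values
    (73.1 kg, 1.71 m, 1.41 m/s), the x2 maximum-isometric-force
    adjustment, and the +/-30 deg in 15 deg steps factorial sweep."""

    subject_mass: float = 73.1
    subject_height: float = 1.71
    walking_velocity: float = 1.41
    fmax_scale: float = 2.0
    sweep_offsets: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    stance_fraction: float = DEFAULT_STANCE_FRACTION
    cadence: float = DEFAULT_CADENCE
    noise_sd: float = 0.0
    seed: int = 0
    region_fraction: float = 0.4
    solver_tol: float = 1e-6
    out_dir: str | None = None

    def __post_init__(self):
        if min(self.subject_mass, self.subject_height,
               self.walking_velocity, self.fmax_scale) <= 0:
            raise ConfigurationError(
                "mass, height, velocity and fmax_scale must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigurationError("stance_fraction must be in (0, 1)")
        self.sweep_offsets = tuple(float(o) for o in self.sweep_offsets)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config YAML must be a mapping")
        return cls.from_dict(data)


@dataclass
class ModelRun:
    """Everything computed for one model of the sweep."""

    model_id: str
    target: GeometryTarget
    model: Model
    kinetics: JointKinetics
    solution: object
    contact: object
    grouped: object
    cci: object
    outcomes: dict[str, float]
    n_infeasible: int


@dataclass
class StudyResult:
    config: StudyConfig
    trial: GaitTrial
    rows: pd.DataFrame
    runs: list[ModelRun]
    errors: dict[str, str]
    reference_model: Model


def _model_id(t: GeometryTarget) -> str:
    return f"ava{t.ava:+.0f}_nsa{t.nsa:.0f}"


def run_single_model(model: Model, trial: GaitTrial,
                     stance_fraction: float) -> ModelRun:
    """Simulate one model on a (cycle-normalized) trial and summarize."""
    kin = inverse_dynamics(model, trial)
    sol = solve_static_optimization(model, trial, kin)
    contact = joint_reaction_analysis(model, trial, sol, kin)
    table = compute_muscle_moments(model, sol, normalize_by_mass=True)
    grouped = group_moments(table)
    cci = cci_series(grouped)

    outcomes: dict[str, float] = {}
    # stance-mean activation per functional muscle group (grouping by each
    # muscle's stance-mean moment arm in the plane, per model)
    for p_i, plane in enumerate(PLANES):
        pos_name, neg_name = PLANE_DIRECTIONS[plane]
        k = model.dof_index(plane)
        roles = [classify_function(sol.moment_arms[:, m_i, k], "stance_mean",
                                   stance_fraction=stance_fraction)
                 for m_i in range(len(model.muscles))]
        for role, out_name in (("agonist", pos_name), ("antagonist", neg_name)):
            members = [i for i, r in enumerate(roles) if r == role]
            if members:
                acts = sol.activations[:, members].mean(axis=1)
                outcomes[f"act_{out_name}"] = stance_mean(
                    acts, stance_fraction)[0]
            else:
                outcomes[f"act_{out_name}"] = float("nan")
        outcomes[f"mom_{pos_name}"] = stance_mean(
            grouped.agonist[:, p_i], stance_fraction)[0]
        outcomes[f"mom_{neg_name}"] = stance_mean(
            grouped.antagonist[:, p_i], stance_fraction)[0]
        outcomes[f"cci_{plane}"] = stance_mean(
            cci.values[:, p_i], stance_fraction)[0]
    for joint in ("hip", "knee", "ankle"):
        outcomes[f"jcf_{joint}_bw"] = stance_mean(
            contact.magnitude_bw[joint], stance_fraction)[0]
    n_infeasible = int((~sol.converged).sum())
    tgt = model.meta.get("deformation", {})
    target = GeometryTarget(tgt.get("target_ava", 18.0),
                            tgt.get("target_nsa", 123.0))
    return ModelRun(model_id=_model_id(target), target=target, model=model,
                    kinetics=kin, solution=sol, contact=contact,
                    grouped=grouped, cci=cci, outcomes=outcomes,
                    n_infeasible=n_infeasible)


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Run the factorial sweep study; deterministic given the config seed.

    Per-model failures are recorded and skipped, not fatal.
    """
    config = config or StudyConfig()
    raw = synthesize_trial(subject_mass=config.subject_mass,
                           walking_velocity=config.walking_velocity,
                           stance_fraction=config.stance_fraction,
                           cadence=config.cadence, noise_sd=config.noise_sd,
                           seed=config.seed,
                           subject_height=config.subject_height)
    cyc = normalize_to_cycle(raw)
    trial = GaitTrial(time=cyc.time, angles=cyc.angles, grf=cyc.grf,
                      cop=cyc.cop, foot_strike=raw.foot_strike,
                      foot_off=raw.foot_off,
                      next_foot_strike=raw.next_foot_strike,
                      subject_mass=raw.subject_mass,
                      walking_velocity=raw.walking_velocity)

    reference = build_template_model(config.subject_mass,
                                     config.subject_height,
                                     config.fmax_scale)
    from .torsion import measure_ava, measure_nsa
    ref_target = GeometryTarget(measure_ava(reference.landmarks),
                                measure_nsa(reference.landmarks))
    spec = SweepSpec(reference=ref_target, offsets=config.sweep_offsets,
                     region_fraction=config.region_fraction)
    sweep = generate_sweep(reference, spec)

    runs: list[ModelRun] = []
    errors: dict[str, str] = {}
    rows = []
    for target, model in sweep:
        mid = _model_id(target)
        t0 = _time.perf_counter()
        try:
            run = run_single_model(model, trial, cyc.stance_fraction)
        except Exception as e:  # noqa: BLE001 - study continues per spec
            logger.error("model %s failed: %s", mid, e)
            errors[mid] = str(e)
            continue
        runs.append(run)
        rows.append({"model_id": mid, "ava": target.ava, "nsa": target.nsa,
                     "n_infeasible": run.n_infeasible, **run.outcomes})
        logger.info("model %s: %.2f s, %d infeasible frames", mid,
                    _time.perf_counter() - t0, run.n_infeasible)
    return StudyResult(config=config, trial=trial,
                       rows=pd.DataFrame(rows), runs=runs, errors=errors,
                       reference_model=reference)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def fit_geometry_regression(rows: pd.DataFrame, outcome: str,
                            alpha: float = 0.05) -> RegressionResult:
    """OLS of a stance-mean outcome on (AVA, NSA) with intercept."""
    if outcome not in rows.columns:
        raise ParameterError(f"outcome column {outcome!r} not present")
    sub = rows[["ava", "nsa", outcome]].dropna()
    if len(sub) < 4:
        raise ParameterError(
            f"need at least 4 non-missing rows for {outcome!r}")
    return fit_ols(sub[outcome].to_numpy(),
                   sub[["ava", "nsa"]].to_numpy(), outcome,
                   ("AVA", "NSA"), alpha=alpha)


def outcome_columns(rows: pd.DataFrame) -> list[str]:
    """The regressable stance-mean outcome columns of a study table."""
    return [c for c in rows.columns
            if c.startswith(("act_", "mom_", "cci_", "jcf_"))]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def regression_table(regressions: list[RegressionResult]) -> pd.DataFrame:
    recs = []
    for r in regressions:
        rec = {"outcome": r.outcome, "r_squared": r.r_squared,
               "f_statistic": r.f_statistic, "f_pvalue": r.f_pvalue,
               "n": r.n}
        for i, name in enumerate(("intercept",) + r.predictor_names):
            rec[f"beta_{name}"] = r.coefficients[i]
            rec[f"se_{name}"] = r.std_errors[i]
            rec[f"p_{name}"] = r.p_values[i]
        recs.append(rec)
    return pd.DataFrame(recs)


def export_results(result: StudyResult,
                   regressions: list[RegressionResult],
                   out_dir: str | Path) -> dict:
    """Write the outcome table, regression summaries, per-model waveform
    archives, config snapshot and a manifest with content hashes."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e

    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False, float_format="%.17g")
        written.append(p)

    _write_csv(result.rows, "outcomes.csv")
    reg_df = regression_table(regressions)
    _write_csv(reg_df, "regressions.csv")
    p = out / "regressions.json"
    p.write_text(json.dumps(reg_df.to_dict(orient="records"), indent=1,
                            default=float))
    written.append(p)
    p = out / "config.json"
    p.write_text(json.dumps(asdict(result.config), indent=1, default=str))
    written.append(p)

    wave_dir = out / "waveforms"
    wave_dir.mkdir(exist_ok=True)
    for run in result.runs:
        df = waveform_table(result, run)
        p = wave_dir / f"{run.model_id}.sto"
        write_motion(p, df, dialect="sto_mot", name=run.model_id)
        written.append(p)

    manifest = {"files": {str(p.relative_to(out)): _sha256(p)
                          for p in written}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def waveform_table(result: StudyResult, run: ModelRun) -> pd.DataFrame:
    """Tidy per-frame table for one model: angles, net moments,
    activations, muscle forces, grouped moments, CCI and contact forces."""
    model = run.model
    cols = {"time": run.kinetics.time}
    for d, w in result.trial.angles.items():
        cols[f"angle_{d}"] = w
    for k, d in enumerate(model.dof_names):
        cols[f"moment_{d}"] = run.kinetics.moments[:, k]
    for i, mname in enumerate(model.muscle_names):
        cols[f"activation_{mname}"] = run.solution.activations[:, i]
        cols[f"force_{mname}"] = run.solution.forces[:, i]
    for p_i, plane in enumerate(PLANES):
        cols[f"m_agonist_{plane}"] = run.grouped.agonist[:, p_i]
        cols[f"m_antagonist_{plane}"] = run.grouped.antagonist[:, p_i]
        cols[f"cci_{plane}"] = run.cci.values[:, p_i]
    for joint in ("hip", "knee", "ankle"):
        cols[f"jcf_{joint}_bw"] = run.contact.magnitude_bw[joint]
    return pd.DataFrame(cols)
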