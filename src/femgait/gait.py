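"""Synthetic one-cycle gait trials.

Emulates the input data of a healthy adult walking barefoot at
self-selected speed (defaults: mass 73.1 kg, height 1.71 m, walking
velocity 1.41 m/s, stance = 60% of the cycle): smooth periodic joint-angle
waveforms reconstructed from truncated Fourier series, a double-bump
vertical ground reaction force (GRF) during stance with exact unloading in
swing, and a center of pressure (COP) that sweeps with the foot.  The
pelvis is the fixed base, so the lab frame translates with the subject and
the stance foot sweeps from anterior to posterior under the body.

Waveform templates are hand-tuned fits qualitatively matching normal-gait
kinematics; they are a stated stand-in, not a claim to equal any measured
trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError

#: conventional fraction of the gait cycle spent in stance
DEFAULT_STANCE_FRACTION = 0.60
#: steps per minute; with 1.41 m/s gives a ~1.08 s stride
DEFAULT_CADENCE = 111.0

_DOF_ORDER = ("hip_flexion", "hip_abduction", "hip_rotation",
              "knee_flexion", "ankle_dorsiflexion")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GaitTrial:
    """One gait cycle: time (s), per-dof angles (deg), GRF (N, ground
    frame), COP (m), gait events (s), subject mass (kg) and walking
    velocity (m/s)."""

    time: np.ndarray
    angles: dict[str, np.ndarray]
    grf: np.ndarray          # (n, 3)
    cop: np.ndarray          # (n, 3)
    foot_strike: float
    foot_off: float
    next_foot_strike: float
    subject_mass: float = 73.1
    walking_velocity: float = 1.41

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.grf = np.asarray(self.grf, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        t0, t1 = self.time[0], self.time[-1]
        for name, ev in (("foot_strike", self.foot_strike),
                         ("foot_off", self.foot_off),
                         ("next_foot_strike", self.next_foot_strike)):
            if not t0 - 1e-9 <= ev <= t1 + 1e-9:
                raise DataError(f"event {name} outside the time span")
        if np.any(self.grf[:, 1] < -1e-9):
            raise DataError("vertical GRF must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time)


@dataclass
class CycleNormalized:
    """Waveforms resampled onto 101 samples (0-100% of the gait cycle)."""

    percent: np.ndarray      # 0..100, 101 samples
    angles: dict[str, np.ndarray]
    grf: np.ndarray
    cop: np.ndarray
    stance_fraction: float
    time: np.ndarray         # resampled absolute time (s)
    subject_mass: float
    walking_velocity: float

    def __post_init__(self):
        if len(self.percent) != 101:
            raise DataError("cycle-normalized arrays must have 101 samples")
        if not 0.0 < self.stance_fraction < 1.0:
            raise DataError("stance_fraction must be in (0, 1)")


@dataclass
class WaveformTemplate:
    """Fourier coefficient sets per dof plus GRF template parameters.

    ``fourier[dof] = (a0, [(a_k, b_k), ...])`` reconstructs
    ``theta(u) = a0 + sum_k a_k cos(2 pi k u) + b_k sin(2 pi k u)`` over the
    cycle fraction u in [0, 1).

    GRF parameters: ``grf_stance_mean_bw`` (stance-phase mean vertical GRF
    in body weights), ``grf_trough_depth`` (relative depth of the mid-stance
    trough shaping the double bump), ``grf_ap_amplitude_bw`` and
    ``grf_ml_amplitude_bw`` (anteroposterior / mediolateral amplitudes).
    """

    fourier: dict[str, tuple[float, list[tuple[float, float]]]]
    grf_stance_mean_bw: float = 0.85
    grf_trough_depth: float = 0.45
    grf_ap_amplitude_bw: float = 0.16
    grf_ml_amplitude_bw: float = 0.04

    def evaluate(self, dof: str, u: np.ndarray) -> np.ndarray:
        a0, harmonics = self.fourier[dof]
        out = np.full_like(np.asarray(u, dtype=float), a0)
        for k, (a, b) in enumerate(harmonics, start=1):
            out += a * np.cos(2 * np.pi * k * u) + b * np.sin(2 * np.pi * k * u)
        return out


# ---------------------------------------------------------------------------
# default template
# ---------------------------------------------------------------------------

#: key points (cycle fraction, degrees) of the default angle waveforms,
#: qualitatively matching healthy-adult gait kinematics
_ANGLE_KNOTS = {
    "hip_flexion": [(0.0, 30), (0.1, 25), (0.3, 5), (0.5, -10), (0.6, -8),
                    (0.75, 15), (0.87, 32), (1.0, 30)],
    "hip_abduction": [(0.0, -2), (0.15, -5), (0.45, -3), (0.6, 2),
                      (0.8, 5), (1.0, -2)],
    "hip_rotation": [(0.0, 3), (0.3, 1), (0.6, -2), (0.8, 0), (1.0, 3)],
    "knee_flexion": [(0.0, 5), (0.12, 18), (0.3, 8), (0.4, 5), (0.5, 12),
                     (0.62, 35), (0.72, 62), (0.82, 45), (0.92, 12),
                     (1.0, 5)],
    "ankle_dorsiflexion": [(0.0, 0), (0.07, -6), (0.3, 8), (0.45, 12),
                           (0.55, -12), (0.65, -18), (0.75, -5), (0.9, 2),
                           (1.0, 0)],
}

_N_HARMONICS = 8


def _fit_fourier(knots, n_harmonics=_N_HARMONICS):
    """Fourier coefficients of the periodic linear interpolant of knots."""
    u_dense = np.linspace(0.0, 1.0, 512, endpoint=False)
    uu = np.array([u for u, _ in knots])
    vv = np.array([v for _, v in knots])
    y = np.interp(u_dense, uu, vv)
    c = np.fft.rfft(y) / len(y)
    a0 = float(c[0].real)
    harm = [(float(2 * c[k].real), float(-2 * c[k].imag))
            for k in range(1, n_harmonics + 1)]
    return a0, harm


def default_waveform_template() -> WaveformTemplate:
    """The packaged healthy-adult waveform template."""
    return WaveformTemplate(
        fourier={dof: _fit_fourier(knots)
                 for dof, knots in _ANGLE_KNOTS.items()})


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _vertical_grf_profile(u_st: np.ndarray, mean_bw: float,
                          trough: float) -> np.ndarray:
    """Double-bump vertical GRF (in BW) versus stance progress in [0, 1].

    sin(pi u)(1 + c cos(2 pi u)) has bumps near 25% and 75% of stance and a
    mid-stance trough; the amplitude is set analytically so the stance-phase
    mean equals ``mean_bw`` (the mean of the shape is 2/pi - c * 2/(3 pi)).
    """
    shape_mean = 2.0 / np.pi - trough * 2.0 / (3.0 * np.pi)
    amp = mean_bw / shape_mean
    return amp * np.sin(np.pi * u_st) * (1.0 + trough * np.cos(2 * np.pi * u_st))


def _smooth_noise(rng: np.random.Generator, u: np.ndarray, sd: float,
                  n_harmonics: int = 3) -> np.ndarray:
    """Band-limited periodic noise with standard deviation ~``sd``."""
    out = np.zeros_like(u)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(size=2)
        out += a * np.cos(2 * np.pi * k * u) + b * np.sin(2 * np.pi * k * u)
    return out * sd / np.sqrt(n_harmonics)


def synthesize_trial(template: WaveformTemplate | None = None,
                     subject_mass: float = 73.1,
                     walking_velocity: float = 1.41,
                     stance_fraction: float = DEFAULT_STANCE_FRACTION,
                     cadence: float = DEFAULT_CADENCE,
                     noise_sd: float = 0.0,
                     seed: int = 0,
                     subject_height: float = 1.71,
                     n_frames: int = 101) -> GaitTrial:
    """Synthesize one full gait cycle.

    The vertical GRF is a double bump during stance and exactly zero during
    swing; angle noise (deg) is band-limited, periodic and seeded, so the
    same seed reproduces the same trial bit for bit.
    """
    if not 0.0 < stance_fraction < 1.0:
        raise ParameterError("stance_fraction must be in (0, 1)")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if subject_mass <= 0 or walking_velocity <= 0 or cadence <= 0:
        raise ParameterError("mass, velocity and cadence must be positive")
    template = template or default_waveform_template()
    rng = np.random.default_rng(seed)

    cycle_t = 120.0 / cadence            # s per stride (two steps)
    time = np.linspace(0.0, cycle_t, n_frames)
    u = time / cycle_t

    angles = {}
    for dof in _DOF_ORDER:
        theta = template.evaluate(dof, u)
        if noise_sd > 0:
            theta = theta + _smooth_noise(rng, u, noise_sd)
        angles[dof] = theta

    bw = subject_mass * 9.81
    stance = u < stance_fraction
    u_st = np.clip(u / stance_fraction, 0.0, 1.0)
    grf = np.zeros((n_frames, 3))
    grf[stance, 1] = bw * _vertical_grf_profile(
        u_st[stance], template.grf_stance_mean_bw, template.grf_trough_depth)
    grf[stance, 0] = -bw * template.grf_ap_amplitude_bw * np.sin(
        2 * np.pi * u_st[stance])
    grf[stance, 2] = -bw * template.grf_ml_amplitude_bw * np.sin(
        np.pi * u_st[stance])

    cop = _synth_cop(angles, u_st, stance, subject_height)

    return GaitTrial(time=time, angles=angles, grf=grf, cop=cop,
                     foot_strike=0.0, foot_off=stance_fraction * cycle_t,
                     next_foot_strike=cycle_t, subject_mass=subject_mass,
                     walking_velocity=walking_velocity)


def _synth_cop(angles: dict, u_st: np.ndarray, stance: np.ndarray,
               height: float) -> np.ndarray:
    """COP consistent with a planar two-link leg under the fixed pelvis:
    the ankle sweeps anterior-to-posterior as the body passes over the
    foot; heel-to-toe progression is added along the foot."""
    l_thigh, l_shank = 0.245 * height, 0.246 * height
    hip_x, hip_y, hip_z = -0.0393 * height, -0.0367 * height, 0.0464 * height
    foot_h = 0.039 * height
    hf = np.deg2rad(angles["hip_flexion"])
    kf = np.deg2rad(angles["knee_flexion"])
    ankle_x = hip_x + l_thigh * np.sin(hf) + l_shank * np.sin(hf - kf)
    ground_y = hip_y - (l_thigh + l_shank + foot_h)
    cop = np.zeros((len(u_st), 3))
    cop[:, 0] = ankle_x + (-0.05 + 0.21 * u_st)
    cop[:, 1] = ground_y
    cop[:, 2] = hip_z
    cop[~stance] = 0.0
    return cop


# ---------------------------------------------------------------------------
# cycle normalization
# ---------------------------------------------------------------------------

def normalize_to_cycle(trial: GaitTrial) -> CycleNormalized:
    """Linear resampling from foot strike to the next foot strike onto 101
    samples (0-100% of the gait cycle)."""
    if not trial.foot_strike < trial.foot_off < trial.next_foot_strike:
        raise DataError("gait events out of order")
    t_new = np.linspace(trial.foot_strike, trial.next_foot_strike, 101)
    angles = {d: np.interp(t_new, trial.time, w)
              for d, w in trial.angles.items()}
    grf = np.column_stack([np.interp(t_new, trial.time, trial.grf[:, i])
                           for i in range(3)])
    cop = np.column_stack([np.interp(t_new, trial.time, trial.cop[:, i])
                           for i in range(3)])
    stance_fraction = ((trial.foot_off - trial.foot_strike)
                       / (trial.next_foot_strike - trial.foot_strike))
    return CycleNormalized(percent=np.linspace(0.0, 100.0, 101),
                           angles=angles, grf=grf, cop=cop,
                           stance_fraction=stance_fraction, time=t_new,
                           subject_mass=trial.subject_mass,
                           walking_velocity=trial.walking_velocity)
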