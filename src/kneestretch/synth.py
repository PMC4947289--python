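"""Synthetic instrumented-assessment datasets with known ground truth.

The generator emulates the study design the package targets: pediatric
TD-like and CP-like subjects, each assessed with a slow (> 5 s) and a fast
(< 1 s) passive knee stretch from ~100 deg flexion to near full extension,
recording knee angle, the examiner's applied wrench, and surface EMG.

Causal structure mirrors the experiment: the examiner's wrench — a
feedforward moment profile plus a hand-impedance correction toward the
intended stretch trajectory — is the generative input.  The "measurement"
is whatever knee motion the true subject model produces under that wrench
(including the stretch reflex for CP fast trials), plus sensor noise.  The
pipeline never sees the truth except as measurement.

EMG is synthesised as amplitude-modulated Gaussian noise: the standard
deviation tracks background level plus a burst term proportional to the
simulated muscle activation, so reflex delay and activation dynamics are
embedded in the channel.  Channels are normalised so the MVC reference RMS
is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .limb import (Anthropometry, SubjectModel, Trial, reference_model,
                   scale_model)
from .passive_fit import muscle_moment_sum
from .reflex import ReflexParams
from .simulate import SimConfig, SimResult, forward_simulate

__all__ = ["SynthConfig", "SubjectTruth", "SyntheticSubject",
           "generate_subject", "generate_trial", "generate_cohort"]

logger = logging.getLogger(__name__)

# Ground-truth passive-parameter distributions (mean, SD) per group.
TRUTH_DISTRIBUTIONS = {
    "TD": {"S_ham": (0.77, 0.15), "K_ham": (3.59, 0.63),
           "S_vas": (4.21, 8.19), "K_vas": (16.12, 15.28)},
    "CP": {"S_ham": (0.57, 0.11), "K_ham": (4.65, 1.27),
           "S_vas": (1.40, 1.73), "K_vas": (8.73, 3.95)},
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.  Identical config + seed => identical dataset."""

    seed: int = 0
    n_td: int = 9
    n_cp: int = 11
    # stretch profiles
    start_angle_deg: float = 100.0
    end_angle_deg: float = 5.0
    slow_duration_s: float = 7.0       # > 5 s of stretch
    fast_stretch_s: float = 0.35       # < 1 s to end range
    fast_record_s: float = 1.0
    slow_rate_hz: float = 200.0
    fast_rate_hz: float = 1000.0
    # examiner hand impedance: stabilises the (gravity-unstable) limb and is
    # firm enough to push through a reflex catch to end range, as examiners do
    hand_kp: float = 40.0              # N*m/rad
    hand_kd: float = 3.0               # N*m*s/rad
    # measurement noise
    angle_noise_deg: float = 0.5
    force_noise_N: float = 0.5
    emg_background: float = 0.02       # MVC fraction
    emg_burst_gain: float = 0.3        # MVC fraction per unit activation
    # reflex truth
    threshold_range: tuple = (0.05, 0.11)   # m/s
    p_gain_zero_cp: float = 1.0 / 11.0
    gain_choices_cp: tuple = (1.0, 2.0, 4.0)
    # model
    tendon_mode: str = "rigid"
    dt: float = 0.001


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    anthropometry: Anthropometry
    S_ham: float
    K_ham: float
    S_vas: float
    K_vas: float
    reflex: ReflexParams
    tendon_mode: str = "rigid"

    @property
    def overrides(self) -> dict:
        return {"HAM": (self.S_ham, self.K_ham), "VAS": (self.S_vas, self.K_vas)}

    def build_model(self) -> SubjectModel:
        return scale_model(reference_model(self.tendon_mode),
                           self.anthropometry).with_passive_overrides(self.overrides)


@dataclass
class SyntheticSubject:
    truth: SubjectTruth
    slow: Trial
    fast: Trial


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_subject(config: SynthConfig, group: str,
                     rng: np.random.Generator,
                     subject_id: Optional[str] = None) -> SubjectTruth:
    """Draw one subject's anthropometry and ground-truth parameters.

    TD subjects have no reflex (G = 0, matching the absence of fast-stretch
    EMG in typically developing children); CP subjects draw G = 0 with a
    small probability and otherwise one of the configured gains.
    """
    if group not in TRUTH_DISTRIBUTIONS:
        raise ValueError(f"group must be TD or CP, got {group!r}")
    mass = _trunc_normal(rng, 34.0, 12.5, 16.0, 60.0)
    height = _trunc_normal(rng, 1.45, 0.15, 1.15, 1.80)
    anthro = Anthropometry(height=height, mass=mass,
                           leg_length=0.485 * height,
                           tibia_length=0.255 * height)
    d = TRUTH_DISTRIBUTIONS[group]
    s_ham = _trunc_normal(rng, *d["S_ham"], 0.2, d["S_ham"][0] + 3 * d["S_ham"][1])
    k_ham = _trunc_normal(rng, *d["K_ham"], 1.0, d["K_ham"][0] + 3 * d["K_ham"][1])
    s_vas = _trunc_normal(rng, *d["S_vas"], 0.5, d["S_vas"][0] + 3 * d["S_vas"][1])
    k_vas = _trunc_normal(rng, *d["K_vas"], 1.0, d["K_vas"][0] + 3 * d["K_vas"][1])
    T = float(rng.uniform(*config.threshold_range))
    if group == "TD":
        G = 0.0
    else:
        G = 0.0 if rng.random() < config.p_gain_zero_cp \
            else float(rng.choice(config.gain_choices_cp))
    return SubjectTruth(
        subject_id=subject_id or f"{group}xx", group=group,
        anthropometry=anthro, S_ham=s_ham, K_ham=k_ham, S_vas=s_vas,
        K_vas=k_vas, reflex=ReflexParams(G=G, T=T),
        tendon_mode=config.tendon_mode)


def _smoothstep(x):
    """Quintic smoothstep with zero velocity and acceleration at both ends."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 3 * (10.0 - 15.0 * x + 6.0 * x * x)


def _desired_profile(config: SynthConfig, speed: str, times: np.ndarray):
    """Intended stretch trajectory theta_d(t) in rad, plus derivatives."""
    th0 = np.deg2rad(config.start_angle_deg)
    th1 = np.deg2rad(config.end_angle_deg)
    if speed == "slow":
        t_start, ramp = 0.3, config.slow_duration_s - 0.6
    else:
        t_start, ramp = 0.05, config.fast_stretch_s
    x = (times - times[0] - t_start) / ramp
    theta = th0 + (th1 - th0) * _smoothstep(x)
    dt = times[1] - times[0]
    omega = np.gradient(theta, dt)
    alpha = np.gradient(omega, dt)
    return theta, omega, alpha


def generate_trial(truth: SubjectTruth, speed: str, config: SynthConfig,
                   rng: np.random.Generator,
                   model: Optional[SubjectModel] = None) -> Trial:
    """Generate one measured trial (slow or fast) for a subject.

    The examiner wrench is a feedforward inverse-dynamics moment along the
    intended trajectory (computed without the reflex) plus a hand-impedance
    correction; the reflex controller with the subject's true gain acts
    during CP fast trials.  Measurement noise is added after simulation and
    never feeds back into the dynamics.
    """
    if speed not in ("slow", "fast"):
        raise ValueError("speed must be 'slow' or 'fast'")
    model = model or truth.build_model()
    dt = config.dt
    duration = config.slow_duration_s if speed == "slow" else config.fast_record_s
    n = int(round(duration / dt)) + 1
    tgrid = dt * np.arange(n)
    theta_d, omega_d, alpha_d = _desired_profile(config, speed, tgrid)

    # feedforward: inverse dynamics of the intended trajectory (no reflex)
    m_static = muscle_moment_sum(model, np.rad2deg(theta_d))
    I = model.shank_foot_inertia
    mgd = model.shank_foot_mass * model.gravity * model.shank_foot_com_distance
    m_ff = I * alpha_d - mgd * np.sin(theta_d) - m_static

    def wrench(t, theta, omega):
        m0 = np.interp(t, tgrid, m_ff)
        th_d = np.interp(t, tgrid, theta_d)
        om_d = np.interp(t, tgrid, omega_d)
        return m0 + config.hand_kp * (th_d - theta) + config.hand_kd * (om_d - omega)

    reflex = truth.reflex if (truth.group == "CP" and speed == "fast"
                              and truth.reflex.G > 0) else None
    sim_cfg = SimConfig(dt=dt, duration=duration)
    # carrier trial: supplies initial pose and the time base; the wrench
    # comes from the examiner model, not from these (zero) columns
    seed_trial = Trial(
        time=tgrid,
        knee_angle_deg=np.full(n, config.start_angle_deg),
        force=np.zeros((n, 3)), moment=np.zeros((n, 3)),
        app_par=np.zeros(n), app_perp=np.zeros(n),
        speed_label=speed, group_label=truth.group)
    sim = forward_simulate(model, seed_trial, None, reflex, sim_cfg,
                           applied_moment_fn=wrench)
    if reflex is None and sim.knee_angle_deg.min() > config.end_angle_deg + 10.0:
        logger.warning("%s %s trial missed end range (min %.1f deg); "
                       "rescaling wrench", truth.subject_id, speed,
                       sim.knee_angle_deg.min())
        boost = 1.2

        def wrench_boosted(t, theta, omega):
            return boost * np.interp(t, tgrid, m_ff) \
                + config.hand_kp * (np.interp(t, tgrid, theta_d) - theta) \
                + config.hand_kd * (np.interp(t, tgrid, omega_d) - omega)

        sim = forward_simulate(model, seed_trial, None, reflex, sim_cfg,
                               applied_moment_fn=wrench_boosted)

    # sample the measurement at the trial rate
    rate = config.slow_rate_hz if speed == "slow" else config.fast_rate_hz
    step = max(int(round(1.0 / (rate * dt))), 1)
    idx = np.arange(0, n, step)
    t_s = sim.time[idx]
    app_par = 0.8 * truth.anthropometry.tibia_length

    if speed == "fast":
        # second pass: re-run the stretch open loop from the recorded wrench
        # through the same code path the analysis pipeline uses, and let THAT
        # be the measurement.  Predicted-vs-measured comparisons then carry
        # no artefact from how the examiner's hand was discretised.
        fy_rec = sim.applied_moment[idx] / app_par
        force0 = np.zeros((len(idx), 3))
        force0[:, 1] = fy_rec
        trial0 = Trial(time=t_s, knee_angle_deg=sim.knee_angle_deg[idx],
                       force=force0, moment=np.zeros((len(idx), 3)),
                       app_par=np.full(len(idx), app_par),
                       app_perp=np.zeros(len(idx)),
                       speed_label=speed, group_label=truth.group)
        sim = forward_simulate(model, trial0, None, reflex, sim_cfg)

    fy = sim.applied_moment[idx] / app_par
    angle = sim.knee_angle_deg[idx] + rng.normal(0.0, config.angle_noise_deg,
                                                 len(idx))
    force = np.zeros((len(idx), 3))
    force[:, 1] = fy + rng.normal(0.0, config.force_noise_N, len(idx))

    floor = model.muscles["HAM"].a_default
    act_ham = sim.activation[idx, sim.muscle_index("HAM")]
    sigma_ham = config.emg_background + config.emg_burst_gain * \
        np.clip(act_ham - floor, 0.0, None) / (1.0 - floor)
    emg_ham = sigma_ham * rng.standard_normal(len(idx))
    emg_rf = config.emg_background * rng.standard_normal(len(idx))

    meta = {
        "subject_id": truth.subject_id,
        "speed_label": speed,
        "group_label": truth.group,
        "anthropometry": asdict(truth.anthropometry),
        "mvc_rms": 1.0,
        "tendon_mode": truth.tendon_mode,
        "truth": {"S_ham": truth.S_ham, "K_ham": truth.K_ham,
                  "S_vas": truth.S_vas, "K_vas": truth.K_vas,
                  "G": truth.reflex.G, "T": truth.reflex.T},
    }
    return Trial(time=t_s, knee_angle_deg=angle, force=force,
                 moment=np.zeros((len(idx), 3)),
                 app_par=np.full(len(idx), app_par),
                 app_perp=np.zeros(len(idx)),
                 emg={"ham": emg_ham, "rf": emg_rf},
                 speed_label=speed, group_label=truth.group, meta=meta)


def generate_cohort(config: SynthConfig) -> list[SyntheticSubject]:
    """Full two-group cohort: per subject a truth record plus one slow and
    one fast trial, reproducible from the config seed."""
    rng = np.random.default_rng(config.seed)
    out = []
    for group, count in (("TD", config.n_td), ("CP", config.n_cp)):
        for i in range(count):
            truth = generate_subject(config, group, rng,
                                     subject_id=f"{group}{i + 1:02d}")
            model = truth.build_model()
            slow = generate_trial(truth, "slow", config, rng, model)
            fast = generate_trial(truth, "fast", config, rng, model)
            out.append(SyntheticSubject(truth, slow, fast))
    return out
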