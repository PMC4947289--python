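"""Forward-dynamic simulation of a passive-stretch trial.

The simulator integrates the coupled skeletal, muscle-activation and (for
elastic tendons) fiber-length dynamics from the trial's measured initial
pose, driving the shank with the recorded applied wrench interpolated in
time.  The stretch-reflex controller runs online: the target muscle's fiber
velocity is buffered every control step and read back with the reflex delay.

Integration is classical fixed-step RK4 at the 1 ms control step, with the
controller excitation frozen within each step (the delay makes the system a
delay-differential equation; the buffer resolution equals the step).  A
step-halving convergence check on the predicted knee angle is part of the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .limb import (MUSCLE_ORDER, SubjectModel, Trial, applied_knee_moment,
                   gravity_moment)
from .muscle import (force_velocity_inverse, solve_fiber_equilibrium)
from .passive_fit import FitResult
from .reflex import GAIN_GRID, ReflexParams, reflex_excitation

__all__ = ["SimConfig", "SimResult", "forward_simulate", "run_gain_sweep"]


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.001                      # control / integration step, s
    duration: Optional[float] = None       # None: 1 s fast, full span slow
    initial_velocity_deg_s: float = 0.0


@dataclass
class SimResult:
    """Logged state trajectories of one forward simulation."""

    time: np.ndarray
    knee_angle_deg: np.ndarray
    knee_velocity_deg_s: np.ndarray
    excitation: np.ndarray        # (n, 5)
    activation: np.ndarray        # (n, 5)
    l_fiber_norm: np.ndarray      # (n, 5)
    v_fiber: np.ndarray           # (n, 5), m/s lengthening +
    muscle_moment: np.ndarray     # (n,) total, N*m flexor +
    applied_moment: np.ndarray = None  # (n,) wrench knee moment used, N*m
    muscle_names: tuple = MUSCLE_ORDER
    diagnostics: dict = field(default_factory=dict)

    def muscle_index(self, name: str) -> int:
        return self.muscle_names.index(name)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time,
            "knee_angle_deg": self.knee_angle_deg,
            "knee_velocity_deg_s": self.knee_velocity_deg_s,
            "muscle_moment_Nm": self.muscle_moment,
        })
        for j, name in enumerate(self.muscle_names):
            df[f"exc_{name.lower()}"] = self.excitation[:, j]
            df[f"act_{name.lower()}"] = self.activation[:, j]
            df[f"lfn_{name.lower()}"] = self.l_fiber_norm[:, j]
            df[f"vf_{name.lower()}_m_s"] = self.v_fiber[:, j]
        return df


class _Engine:
    """Vectorised per-muscle constants and the system right-hand side."""

    def __init__(self, model: SubjectModel):
        self.model = model
        ms = [model.muscles[n] for n in MUSCLE_ORDER]
        gs = [model.geometry[n] for n in MUSCLE_ORDER]
        modes = {p.tendon_mode for p in ms}
        if len(modes) > 1:
            raise ValueError("all muscles must share one tendon mode")
        self.elastic = modes.pop() == "elastic"
        arr = lambda attr: np.array([getattr(p, attr) for p in ms])
        self.F0 = arr("F_iso_max")
        self.lopt = arr("l_opt")
        self.lslack = arr("l_slack")
        self.S = arr("S")
        self.K = arr("K")
        self.gamma = arr("gamma")
        self.vmax = arr("v_max")
        self.flen = arr("f_len_max")
        self.eps0 = arr("tendon_strain_iso")
        self.tau_a = arr("tau_act")
        self.tau_d = arr("tau_deact")
        self.floor = arr("a_default")
        self.a0 = np.array([g.a0 for g in gs])
        self.a1 = np.array([g.a1 for g in gs])
        self.a2 = np.array([g.a2 for g in gs])
        self.expm1K = np.expm1(self.K)
        # tendon toe constants
        self.eps_toe = 0.609 * self.eps0
        self.k_lin = (1.0 - 0.33) / (self.eps0 - self.eps_toe)

    # inlined curve evaluations (hot path)
    def _fpe(self, L):
        return np.expm1(self.K * np.clip(L - 1.0, 0.0, None) / self.S) / self.expm1K

    def _fl(self, L):
        return np.exp(-((L - 1.0) ** 2) / self.gamma)

    def _fv(self, u):
        conc = np.where(u <= -1.0, 0.0,
                        (1.0 + u) / (1.0 - np.minimum(u, 0.0) * 4.0))
        ae = (self.flen - 1.0) / 5.0
        ecc = (1.0 + u * self.flen / ae) / (1.0 + u / ae)
        return np.clip(np.where(u < 0.0, conc, ecc), 0.0, self.flen)

    def _ftendon(self, eps):
        toe = 0.33 * np.expm1(3.0 * np.clip(eps, 0.0, None) / self.eps_toe) / np.expm1(3.0)
        lin = 0.33 + self.k_lin * (eps - self.eps_toe)
        return np.where(eps <= 0.0, 0.0, np.where(eps < self.eps_toe, toe, lin))

    def rhs(self, theta, omega, act, lnorm, exc, m_app):
        """Returns (domega ... full derivative tuple, aux dict)."""
        lmt = self.a0 + self.a1 * theta + self.a2 * theta * theta
        arm = -(self.a1 + 2.0 * self.a2 * theta)
        v_mt = -arm * omega
        if self.elastic:
            eps = (lmt - lnorm * self.lopt) / self.lslack - 1.0
            ft = self._ftendon(eps)
            denom = np.maximum(act * self._fl(lnorm), 1e-4)
            fv_req = (ft - self._fpe(lnorm)) / denom
            u = force_velocity_inverse(np.clip(fv_req, 0.0, self.flen - 0.01),
                                       v_max=1.0, f_len_max=1.4) * self.vmax
            dlnorm = u
            v_fib = u * self.lopt
            force = self.F0 * ft
        else:
            lnorm = np.maximum((lmt - self.lslack) / self.lopt, 1e-3)
            v_fib = v_mt
            u = v_fib / (self.lopt * self.vmax)
            f = act * self._fl(lnorm) * self._fv(u) + self._fpe(lnorm)
            force = np.where(lmt - self.lslack <= 0.0, 0.0, self.F0 * f)
            dlnorm = np.zeros_like(lnorm)
        m_mus = float(np.dot(arm, force))
        m = self.model
        m_grav = m.shank_foot_mass * m.gravity * m.shank_foot_com_distance * np.sin(theta)
        m_lim = 0.0
        if theta < 0.0:
            m_lim = -m.limit_stiffness * theta - m.limit_damping * omega
        domega = (m_mus + m_grav + m_app + m_lim) / m.shank_foot_inertia
        u_eff = np.maximum(exc, self.floor)
        dact = (u_eff - act) / np.where(u_eff > act, self.tau_a, self.tau_d)
        aux = {"v_fiber": v_fib, "l_fiber_norm": lnorm, "moment": m_mus,
               "limit": m_lim != 0.0}
        return omega, domega, dact, dlnorm, aux


def _interp_wrench(trial: Trial, times: np.ndarray) -> np.ndarray:
    """Applied knee moment at arbitrary times; zero outside the record."""
    m_app = applied_knee_moment(trial.force, trial.moment,
                                trial.app_par, trial.app_perp)
    out = np.interp(times, trial.time, m_app, left=0.0, right=0.0)
    # np.interp clamps; force true zero outside the recorded span
    out[(times < trial.time[0] - 1e-12) | (times > trial.time[-1] + 1e-12)] = 0.0
    return out


def forward_simulate(model: SubjectModel, trial: Trial,
                     fit_result: FitResult | dict | None = None,
                     reflex_params: ReflexParams | None = None,
                     config: SimConfig | None = None,
                     applied_moment_fn=None) -> SimResult:
    """Integrate the model forward through one trial.

    Parameters
    ----------
    fit_result : FitResult, dict or None
        Subject-specific passive (S, K) overrides applied before simulating.
    reflex_params : ReflexParams or None
        Stretch-reflex controller; ``None`` (or ``enabled=False`` or G = 0)
        leaves all excitations at zero.

    The initial knee angle is the trial's first sample; initial velocity is
    configurable (default 0); activations start at the resting level and
    elastic fiber lengths at static equilibrium.

    ``applied_moment_fn(t, theta_rad, omega_rad_s) -> N*m`` optionally
    replaces the trial's recorded wrench (used by the synthetic-trial
    generator to emulate the examiner's hand, which reacts to the limb);
    it is evaluated at each control step and frozen over the step.  The
    applied moment actually used is logged in ``SimResult.applied_moment``.
    """
    cfg = config or SimConfig()
    if fit_result is not None:
        overrides = fit_result.overrides if isinstance(fit_result, FitResult) \
            else fit_result
        model = model.with_passive_overrides(overrides)
    eng = _Engine(model)

    duration = cfg.duration
    if duration is None:
        duration = 1.0 if trial.speed_label == "fast" else \
            float(trial.time[-1] - trial.time[0])
    dt = cfg.dt
    n = int(round(duration / dt)) + 1
    t0 = float(trial.time[0])
    times = t0 + dt * np.arange(n)
    m_app_full = _interp_wrench(trial, t0 + dt * np.arange(2 * n) / 2.0)

    theta = float(np.deg2rad(trial.knee_angle_deg[0]))
    omega = float(np.deg2rad(cfg.initial_velocity_deg_s))
    act = eng.floor.copy()
    if eng.elastic:
        lnorm = np.array([
            solve_fiber_equilibrium(model.muscles[nme],
                                    model.geometry[nme].length(theta),
                                    model.muscles[nme].a_default)[0]
            for nme in MUSCLE_ORDER])
    else:
        lnorm = np.zeros(5)

    reflex_on = (reflex_params is not None and reflex_params.enabled
                 and reflex_params.G > 0.0)
    if reflex_on:
        tgt = MUSCLE_ORDER.index(reflex_params.target_muscle)
        delay_steps = reflex_params.t_d / dt

    out_ang = np.empty(n); out_vel = np.empty(n)
    out_exc = np.zeros((n, 5)); out_act = np.empty((n, 5))
    out_lfn = np.empty((n, 5)); out_vf = np.empty((n, 5))
    out_mom = np.empty(n); out_app = np.empty(n)
    v_hist = np.zeros(n)
    n_limit = 0

    exc = np.zeros(5)
    exc_mid = np.zeros(5)
    exc_end = np.zeros(5)
    for i in range(n):
        t = times[i]
        if reflex_on:
            # delayed, linearly interpolated reads of the velocity buffer
            # (buffer holds steps 0 .. i-1; warm-up outputs zero); the
            # controller output is also evaluated at the RK substep times
            def _delayed(pos):
                if pos < 0 or i == 0:
                    return 0.0
                j = min(int(pos), i - 1)
                j2 = min(j + 1, i - 1)
                fr = min(pos - j, 1.0)
                v_del = (1.0 - fr) * v_hist[j] + fr * v_hist[j2]
                return reflex_excitation(v_del, reflex_params)

            exc = np.zeros(5)
            exc_mid = np.zeros(5)
            exc_end = np.zeros(5)
            exc[tgt] = _delayed(i - delay_steps)
            exc_mid[tgt] = _delayed(i + 0.5 - delay_steps)
            exc_end[tgt] = _delayed(i + 1.0 - delay_steps)

        if applied_moment_fn is not None:
            # time-varying part sampled at the substep times; the state
            # arguments stay at the step-start state (frozen like excitation)
            m_now = float(applied_moment_fn(t, theta, omega))
            m_mid = float(applied_moment_fn(t + 0.5 * dt, theta, omega))
            m_end = float(applied_moment_fn(t + dt, theta, omega))
        else:
            m_now = m_app_full[2 * i]
            m_mid = m_app_full[min(2 * i + 1, 2 * n - 1)]
            m_end = m_app_full[min(2 * i + 2, 2 * n - 1)]
        k1 = eng.rhs(theta, omega, act, lnorm, exc, m_now)
        aux = k1[4]
        # log state at t
        out_ang[i] = np.rad2deg(theta)
        out_vel[i] = np.rad2deg(omega)
        out_exc[i] = exc
        out_act[i] = act
        out_lfn[i] = aux["l_fiber_norm"]
        out_vf[i] = aux["v_fiber"]
        out_mom[i] = aux["moment"]
        out_app[i] = m_now
        v_hist[i] = aux["v_fiber"][tgt] if reflex_on else 0.0
        n_limit += int(aux["limit"])
        if i == n - 1:
            break

        h = dt
        k2 = eng.rhs(theta + 0.5 * h * k1[0], omega + 0.5 * h * k1[1],
                     act + 0.5 * h * k1[2], lnorm + 0.5 * h * k1[3],
                     exc_mid, m_mid)
        k3 = eng.rhs(theta + 0.5 * h * k2[0], omega + 0.5 * h * k2[1],
                     act + 0.5 * h * k2[2], lnorm + 0.5 * h * k2[3],
                     exc_mid, m_mid)
        k4 = eng.rhs(theta + h * k3[0], omega + h * k3[1],
                     act + h * k3[2], lnorm + h * k3[3], exc_end, m_end)
        theta += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        omega += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        act = np.clip(act + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
                      eng.floor, 1.0)
        if eng.elastic:
            lnorm = np.clip(
                lnorm + h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
                1e-3, 2.5)

    return SimResult(
        time=times, knee_angle_deg=out_ang, knee_velocity_deg_s=out_vel,
        excitation=out_exc, activation=out_act, l_fiber_norm=out_lfn,
        v_fiber=out_vf, muscle_moment=out_mom, applied_moment=out_app,
        diagnostics={"dt": dt, "n_steps": n, "limit_engaged_steps": n_limit,
                     "tendon_mode": "elastic" if eng.elastic else "rigid"})


def run_gain_sweep(model: SubjectModel, trial: Trial,
                   fit_result: FitResult | dict | None,
                   base_reflex: ReflexParams,
                   config: SimConfig | None = None,
                   gains: Sequence[float] = GAIN_GRID) -> Dict[float, SimResult]:
    """Simulate a fast trial at each reflex gain, everything else shared."""
    from .reflex import gain_grid as _grid
    results = {}
    for rp in _grid(base_reflex, gains):
        results[rp.G] = forward_simulate(model, trial, fit_result, rp, config)
    return results
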