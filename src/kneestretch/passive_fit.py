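"""The contracture model: estimating passive stiffness parameters S and K.

Contracture is represented as altered passive force-length properties of
the hamstrings and vasti.  Their (S, K) pairs are found by matching the
summed static muscle moments of all five lumped muscles to the net knee
moment-angle curve from inverse dynamics of a slow stretch, minimising the
RMS moment error with a derivative-free Nelder-Mead simplex started at the
generic defaults (S = 0.6, K = 4) for both muscles.

The search runs in log-parameter space: the simplex itself is unbounded
while S and K stay positive (negative values are physically meaningless and
undefined in the exponential passive curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .limb import MUSCLE_ORDER, SubjectModel, mt_length_and_arm
from .muscle import (active_force_length_norm, force_velocity_norm,
                     passive_force_norm, solve_fiber_equilibrium)

__all__ = ["FitResult", "muscle_moment_sum", "fit_passive_params"]

DEFAULT_START = (0.6, 4.0, 0.6, 4.0)  # S_ham, K_ham, S_vas, K_vas


@dataclass
class FitResult:
    """Outcome of one subject's passive-parameter optimisation."""

    S_ham: float
    K_ham: float
    S_vas: float
    K_vas: float
    rms_error: float          # N*m
    n_iterations: int
    converged: bool
    start_point: tuple = DEFAULT_START

    @property
    def overrides(self) -> dict:
        return {"HAM": (self.S_ham, self.K_ham), "VAS": (self.S_vas, self.K_vas)}

    def to_dict(self) -> dict:
        return {
            "S_ham": self.S_ham, "K_ham": self.K_ham,
            "S_vas": self.S_vas, "K_vas": self.K_vas,
            "rms_error_Nm": self.rms_error,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "start_point": list(self.start_point),
        }


def muscle_moment_sum(model: SubjectModel, knee_angle_deg, overrides=None,
                      activation: float = 0.01, omega_deg_s=None):
    """Total muscle knee moment (N*m, flexor positive) at measured states.

    The "muscle analysis" step of the fitting loop: each lumped muscle is
    evaluated at resting activation with (S, K) optionally overridden.  When
    ``omega_deg_s`` is given (rigid tendon), the force-velocity scaling of
    the active term is evaluated at the fiber velocity implied by the knee
    velocity — the analysis consumes the measured motion states, not an
    isometric idealisation.  Omitted (or elastic tendon), the evaluation is
    isometric.  Vectorised over angles.
    """
    overrides = overrides or {}
    ang = np.asarray(knee_angle_deg, dtype=float)
    total = np.zeros_like(np.atleast_1d(ang), dtype=float)
    omega = None if omega_deg_s is None else \
        np.deg2rad(np.atleast_1d(np.asarray(omega_deg_s, dtype=float)))
    for name in MUSCLE_ORDER:
        p = model.muscles[name]
        if name in overrides:
            p = p.with_passive(*overrides[name])
        l_mt, arm = mt_length_and_arm(model, name, ang)
        l_mt = np.atleast_1d(l_mt)
        arm = np.atleast_1d(arm)
        if p.tendon_mode == "rigid":
            l_norm = np.maximum((l_mt - p.l_slack) / p.l_opt, 1e-3)
            fv = 1.0
            if omega is not None:
                v_norm = -arm * omega / p.l_opt  # lengthening +, l_opt/s
                fv = force_velocity_norm(v_norm, 1.0, p.v_max, p.f_len_max)
            f_norm = (activation * active_force_length_norm(l_norm, p.gamma) * fv
                      + passive_force_norm(l_norm, p.S, p.K))
            force = np.where((l_mt - p.l_slack) <= 0, 0.0, p.F_iso_max * f_norm)
        else:
            _, force = solve_fiber_equilibrium(p, l_mt, activation)
        total += arm * force
    return total if np.ndim(knee_angle_deg) else float(total[0])


def fit_passive_params(model: SubjectModel, curve: pd.DataFrame,
                       start=DEFAULT_START, activation: float = 0.01,
                       max_iter: int = 2000, xatol: float = 1e-4,
                       fatol: float = 1e-6) -> FitResult:
    """Fit (S, K) of HAM and VAS to a net moment-angle curve.

    Parameters
    ----------
    curve : DataFrame
        Uniform-angle-grid curve with ``angle_deg`` and ``moment_Nm``
        columns (see :func:`kneestretch.invdyn.moment_angle_curve`).
    start : tuple
        (S_ham, K_ham, S_vas, K_vas) starting values for the simplex.

    Notes
    -----
    The RMS objective lives on the angle grid, so the fit weighs the curve,
    not the time spent at each angle.  Convergence tolerances are below the
    reporting precision of the parameters.
    """
    angles = np.asarray(curve["angle_deg"], dtype=float)
    target = np.asarray(curve["moment_Nm"], dtype=float)
    omega = np.asarray(curve["omega_deg_s"], dtype=float) \
        if "omega_deg_s" in curve else None
    if len(angles) < 8:
        raise ValueError("moment-angle curve too short to fit")
    if angles.min() > 20.0:
        warnings.warn(
            "curve does not reach within 20 deg of full extension; the "
            "hamstrings toe region is poorly covered and S/K may be weakly "
            "identified")

    def objective(logx):
        s_h, k_h, s_v, k_v = np.exp(logx)
        m = muscle_moment_sum(model, angles,
                              {"HAM": (s_h, k_h), "VAS": (s_v, k_v)},
                              activation, omega)
        return float(np.sqrt(np.mean((m - target) ** 2)))

    x0 = np.log(np.asarray(start, dtype=float))
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "maxfev": 4 * max_iter,
                            "xatol": xatol, "fatol": fatol})
    s_h, k_h, s_v, k_v = np.exp(res.x)
    return FitResult(S_ham=float(s_h), K_ham=float(k_h),
                     S_vas=float(s_v), K_vas=float(k_v),
                     rms_error=float(res.fun), n_iterations=int(res.nit),
                     converged=bool(res.success), start_point=tuple(start))
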