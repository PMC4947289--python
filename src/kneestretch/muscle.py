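"""Hill-type (Thelen-style) muscle-tendon mechanics.

The muscle model used throughout the package is the classic lumped-parameter
Hill model: a contractile element with active force-length and force-velocity
scaling, a parallel passive elastic element, and an in-series tendon that is
either rigid or elastic.

The passive element is the exponential toe curve

    F_pe(L) = (exp(K * (L - 1) / S) - 1) / (exp(K) - 1)      for L > 1,

with ``L`` the fiber length normalised to optimal fiber length, ``S`` the
passive strain at which passive force equals maximum isometric force
(``F_pe(1 + S) = 1`` by construction), and ``K`` the exponential shape
factor.  ``S`` and ``K`` are the two subject-specific parameters the
contracture model estimates; everything else is held at standard values.

Sign conventions: fiber velocity is positive when lengthening, in m/s;
normalised fiber velocity is in optimal fiber lengths per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "MuscleParams",
    "MuscleState",
    "passive_force_norm",
    "active_force_length_norm",
    "force_velocity_norm",
    "force_velocity_inverse",
    "tendon_force_norm",
    "tendon_strain_from_force",
    "activation_dynamics_step",
    "activation_rate",
    "muscle_force",
    "solve_fiber_equilibrium",
]

# Hill force-velocity constants (dimensionless).  AF is the Hill shape
# parameter of the concentric hyperbola; FLEN the eccentric force plateau.
# AE is fixed so the eccentric branch is C1-continuous with the concentric
# branch at zero velocity (shared slope 1 + 1/AF).
_AF = 0.25
_FLEN_DEFAULT = 1.4

# Thelen tendon: exponential toe up to strain EPS_TOE_FRAC*eps0, then linear,
# renormalised to reach exactly 1 at the nominal isometric strain eps0.
_F_TOE = 0.33
_K_TOE = 3.0
_EPS_TOE_FRAC = 0.609


@dataclass
class MuscleParams:
    """Constants of one lumped muscle-tendon actuator.

    Attributes
    ----------
    name : str
        Muscle label (HAM, VAS, RF, BFS, GAS).
    F_iso_max : float
        Maximum isometric force, N.
    l_opt : float
        Optimal fiber length, m.
    l_slack : float
        Tendon slack length, m.
    S, K : float
        Passive force-length parameters (strain at max isometric force and
        exponential shape factor).
    gamma : float
        Width of the Gaussian active force-length curve.
    v_max : float
        Maximum shortening velocity, optimal fiber lengths / s.
    tau_act, tau_deact : float
        Activation / deactivation time constants, s.
    a_default : float
        Resting activation; also the hard lower bound on activation.
    tendon_mode : {"rigid", "elastic"}
    """

    name: str
    F_iso_max: float
    l_opt: float
    l_slack: float
    S: float = 0.6
    K: float = 4.0
    gamma: float = 0.45
    v_max: float = 10.0
    tau_act: float = 0.01
    tau_deact: float = 0.04
    a_default: float = 0.01
    tendon_mode: Literal["rigid", "elastic"] = "elastic"
    f_len_max: float = _FLEN_DEFAULT
    tendon_strain_iso: float = 0.033

    def __post_init__(self) -> None:
        if self.F_iso_max <= 0 or self.l_opt <= 0 or self.l_slack < 0:
            raise ValueError(
                f"{self.name}: F_iso_max and l_opt must be > 0, l_slack >= 0"
            )
        if self.S <= 0 or self.K <= 0:
            raise ValueError(f"{self.name}: S and K must be positive")
        if not 0 < self.a_default < 1:
            raise ValueError(f"{self.name}: a_default must lie in (0, 1)")

    def with_passive(self, S: float, K: float) -> "MuscleParams":
        """Copy with overridden passive parameters."""
        return replace(self, S=S, K=K)


@dataclass
class MuscleState:
    """Instantaneous fiber state.

    activation in [a_default, 1]; l_fiber_norm = fiber length / l_opt;
    v_fiber in m/s, lengthening positive.
    """

    activation: float
    l_fiber_norm: float
    v_fiber: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation outside [0, 1]")
        if self.l_fiber_norm <= 0:
            raise ValueError("l_fiber_norm must be positive")


def passive_force_norm(l_fiber_norm, S, K):
    """Normalised passive fiber force.

    Exponential toe curve, clamped to zero at and below optimal length
    (a slack fiber carries no passive force).  Equals 1 exactly at
    ``l_fiber_norm = 1 + S``.
    """
    S = np.asarray(S, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(S <= 0) or np.any(K <= 0):
        raise ValueError("S and K must be positive")
    L = np.asarray(l_fiber_norm, dtype=float)
    strain = np.clip(L - 1.0, 0.0, None)
    # exponent grouped as K*(strain/S): at strain == S the ratio is exactly 1
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.expm1(K * (strain / S)) / np.expm1(K)
        # for exponents past float range use the asymptotic ratio e^(K(x-1))
        bad = ~np.isfinite(out)
        if np.any(bad):
            out = np.where(bad, np.exp(K * (strain / S - 1.0)), out)
    return out if out.ndim else float(out)


def active_force_length_norm(l_fiber_norm, gamma=0.45):
    """Gaussian active force-length scale, peak 1 at optimal length."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    L = np.asarray(l_fiber_norm, dtype=float)
    out = np.exp(-((L - 1.0) ** 2) / gamma)
    return out if out.ndim else float(out)


def _ae(f_len_max: float) -> float:
    return (f_len_max - 1.0) / (1.0 + 1.0 / _AF)


def force_velocity_norm(v_fiber_norm, activation=1.0, v_max=10.0,
                        f_len_max=_FLEN_DEFAULT):
    """Normalised force-velocity scale.

    ``v_fiber_norm`` is in optimal fiber lengths per second, lengthening
    positive.  Classic Hill hyperbola when shortening (zero force at
    ``-v_max``), saturating eccentric branch bounded by ``f_len_max``.
    The two branches share slope ``1 + 1/Af`` at zero velocity.
    ``activation`` is accepted for interface symmetry; the curve itself is
    activation-independent here (no velocity scaling with activation).
    """
    u = np.asarray(v_fiber_norm, dtype=float) / v_max
    ae = _ae(f_len_max)
    conc = np.where(u <= -1.0, 0.0, (1.0 + u) / (1.0 - np.minimum(u, 0.0) / _AF))
    ecc = (1.0 + u * f_len_max / ae) / (1.0 + u / ae)
    out = np.where(u < 0.0, conc, ecc)
    out = np.clip(out, 0.0, f_len_max)
    return out if out.ndim else float(out)


def force_velocity_inverse(f_v, v_max=10.0, f_len_max=_FLEN_DEFAULT):
    """Normalised fiber velocity (l_opt/s, lengthening +) for a required
    force-velocity multiplier, the inverse of :func:`force_velocity_norm`.

    The multiplier is clamped into ``[0, f_len_max - 0.01]`` so the inverse
    stays finite near the eccentric plateau.
    """
    f = np.clip(np.asarray(f_v, dtype=float), 0.0, f_len_max - 0.01)
    ae = _ae(f_len_max)
    u_conc = (f - 1.0) / (1.0 + f / _AF)
    u_ecc = ae * (f - 1.0) / (f_len_max - f)
    u = np.where(f < 1.0, u_conc, u_ecc)
    out = u * v_max
    return out if out.ndim else float(out)


def tendon_force_norm(strain, strain_iso=0.033):
    """Normalised tendon force from tendon strain (l/l_slack - 1).

    Exponential toe followed by a linear region; zero for slack tendon and
    exactly 1 at the nominal isometric strain ``strain_iso``.
    """
    eps = np.asarray(strain, dtype=float)
    eps_toe = _EPS_TOE_FRAC * strain_iso
    k_lin = (1.0 - _F_TOE) / (strain_iso - eps_toe)
    toe = _F_TOE * np.expm1(_K_TOE * np.clip(eps, 0.0, None) / eps_toe) / np.expm1(_K_TOE)
    lin = _F_TOE + k_lin * (eps - eps_toe)
    out = np.where(eps <= 0.0, 0.0, np.where(eps < eps_toe, toe, lin))
    return out if out.ndim else float(out)


def tendon_strain_from_force(f_norm, strain_iso=0.033):
    """Inverse of :func:`tendon_force_norm` (zero force maps to zero strain)."""
    f = np.asarray(f_norm, dtype=float)
    eps_toe = _EPS_TOE_FRAC * strain_iso
    k_lin = (1.0 - _F_TOE) / (strain_iso - eps_toe)
    toe = eps_toe / _K_TOE * np.log1p(np.clip(f, 0.0, None) * np.expm1(_K_TOE) / _F_TOE)
    lin = eps_toe + (f - _F_TOE) / k_lin
    out = np.where(f <= 0.0, 0.0, np.where(f < _F_TOE, toe, lin))
    return out if out.ndim else float(out)


def activation_rate(excitation, activation, tau_act=0.01, tau_deact=0.04,
                    floor=0.01):
    """First-order activation dynamics rate da/dt.

    The effective drive is ``max(excitation, floor)`` so activation never
    decays below the resting level; the time constant switches between
    activation and deactivation depending on the sign of the drive error.
    """
    u = np.maximum(np.asarray(excitation, dtype=float), floor)
    a = np.asarray(activation, dtype=float)
    tau = np.where(u > a, tau_act, tau_deact)
    out = (u - a) / tau
    return out if out.ndim else float(out)


def activation_dynamics_step(excitation, activation, dt, tau_act=0.01,
                             tau_deact=0.04, floor=0.01):
    """Advance activation by ``dt`` using the exact exponential solution of
    the first-order dynamics with constant excitation over the step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.maximum(np.asarray(excitation, dtype=float), floor)
    a = np.asarray(activation, dtype=float)
    tau = np.where(u > a, tau_act, tau_deact)
    new = u + (a - u) * np.exp(-dt / tau)
    out = np.clip(new, floor, 1.0)
    return out if out.ndim else float(out)


def _fiber_force_norm(p: MuscleParams, l_norm, activation, v_norm):
    fl = active_force_length_norm(l_norm, p.gamma)
    fv = force_velocity_norm(v_norm, activation, p.v_max, p.f_len_max)
    return activation * fl * fv + passive_force_norm(l_norm, p.S, p.K)


def solve_fiber_equilibrium(params: MuscleParams, l_mt, activation=None,
                            n_iter=70):
    """Static elastic-tendon equilibrium fiber length.

    Solves ``a*f_L(L) + F_pe(L) = F_T((l_mt - L*l_opt - l_slack)/l_slack)``
    for the normalised fiber length ``L`` at zero fiber velocity, by
    vectorised bisection (the tendon side is strictly decreasing in ``L``).

    Returns
    -------
    l_norm : ndarray or float
        Equilibrium normalised fiber length.
    force : ndarray or float
        Tendon force, N.
    """
    a = params.a_default if activation is None else activation
    l_mt = np.asarray(l_mt, dtype=float)
    scalar = l_mt.ndim == 0
    l_mt = np.atleast_1d(l_mt)

    def resid(L):
        eps = (l_mt - L * params.l_opt) / params.l_slack - 1.0
        return (a * active_force_length_norm(L, params.gamma)
                + passive_force_norm(L, params.S, params.K)
                - tendon_force_norm(eps, params.tendon_strain_iso))

    lo = np.full_like(l_mt, 1e-6)
    hi = l_mt / params.l_opt
    slackish = l_mt <= params.l_slack
    r_lo = resid(lo)
    # if the muscle side already exceeds the fully stretched tendon force the
    # bracket is degenerate (tendon cannot balance); pin to the lower bound
    bad = r_lo > 0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r = resid(mid)
        lo = np.where(r < 0, mid, lo)
        hi = np.where(r < 0, hi, mid)
    l_norm = 0.5 * (lo + hi)
    eps = (l_mt - l_norm * params.l_opt) / params.l_slack - 1.0
    force = params.F_iso_max * tendon_force_norm(eps, params.tendon_strain_iso)
    l_norm = np.where(slackish | bad, np.maximum((l_mt - params.l_slack)
                                                 / params.l_opt, 1e-3), l_norm)
    force = np.where(slackish | bad, 0.0, force)
    resid_n = np.abs(resid(l_norm)) * params.F_iso_max
    if np.any(~(slackish | bad) & (resid_n > 1e-6)):
        raise RuntimeError(
            f"{params.name}: tendon equilibrium failed, max residual "
            f"{resid_n.max():.3e} N at l_mt={l_mt[np.argmax(resid_n)]:.4f} m")
    if scalar:
        return float(l_norm[0]), float(force[0])
    return l_norm, force


def muscle_force(params: MuscleParams, l_mt, activation=None, v_fiber=0.0,
                 l_fiber_norm=None):
    """Tendon force of one muscle at muscle-tendon length ``l_mt``.

    Rigid tendon: fiber length is ``l_mt - l_slack`` and the force is
    ``F_iso_max * (a*f_L*f_v + F_pe)`` directly.

    Elastic tendon: if ``l_fiber_norm`` is given the tendon force follows
    from the tendon strain; otherwise the static equilibrium (zero fiber
    velocity) is solved first.

    Returns ``(force_N, MuscleState)``.
    """
    a = params.a_default if activation is None else float(activation)
    if params.tendon_mode == "rigid":
        l_norm = (np.asarray(l_mt, dtype=float) - params.l_slack) / params.l_opt
        v_norm = np.asarray(v_fiber, dtype=float) / params.l_opt
        f = _fiber_force_norm(params, np.maximum(l_norm, 1e-3), a, v_norm)
        force = np.where(l_norm <= 0, 0.0, params.F_iso_max * f)
        force = force if force.ndim else float(force)
        l_rep = float(np.atleast_1d(l_norm)[0])
        return force, MuscleState(a, max(l_rep, 1e-3), float(np.atleast_1d(v_fiber)[0]))
    if l_fiber_norm is None:
        l_norm, force = solve_fiber_equilibrium(params, l_mt, a)
        l_rep = float(np.atleast_1d(l_norm)[0])
        return force, MuscleState(a, l_rep, 0.0)
    eps = (np.asarray(l_mt, dtype=float)
           - np.asarray(l_fiber_norm, dtype=float) * params.l_opt) / params.l_slack - 1.0
    force = params.F_iso_max * tendon_force_norm(eps, params.tendon_strain_iso)
    force = force if np.ndim(force) else float(force)
    return force, MuscleState(a, float(np.atleast_1d(l_fiber_norm)[0]),
                              float(np.atleast_1d(v_fiber)[0]))
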