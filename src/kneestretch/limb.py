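"""Subject-scaled 1-DOF knee model for supine passive-stretch assessment.

Posture: subject supine, pelvis and thigh fixed with the hip flexed 90 deg,
so the thigh points vertically and the shank+foot segment rotates about the
knee axis.  Knee angle convention: flexion positive, 0 deg = full anatomical
extension; a stretch trial moves from high flexion toward 0.

With the shank at knee flexion theta, the segment makes angle theta with the
upward vertical, so gravity produces the flexion-positive moment
``m*g*d*sin(theta)`` (the shank falls into flexion when released).

Muscle geometry is a swappable set of per-muscle quadratic polynomials
``l_MT(theta)`` (theta in radians); the knee moment arm follows from virtual
work as ``r(theta) = -d l_MT / d theta``, positive for knee flexors (HAM,
BFS, GAS) and negative for extensors (VAS, RF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .muscle import MuscleParams

__all__ = [
    "GRAVITY",
    "Anthropometry",
    "MuscleGeometry",
    "SubjectModel",
    "Trial",
    "reference_model",
    "REFERENCE_ANTHROPOMETRY",
    "scale_model",
    "mt_length_and_arm",
    "gravity_moment",
    "applied_knee_moment",
    "equation_of_motion",
]

GRAVITY = 9.81

MUSCLE_ORDER = ("HAM", "VAS", "RF", "BFS", "GAS")


@dataclass(frozen=True)
class Anthropometry:
    """Subject dimensions used for model scaling (all in SI)."""

    height: float
    mass: float
    leg_length: float
    tibia_length: float

    def __post_init__(self) -> None:
        for name in ("height", "mass", "leg_length", "tibia_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.leg_length <= self.tibia_length:
            raise ValueError("leg_length must exceed tibia_length")


@dataclass(frozen=True)
class MuscleGeometry:
    """Quadratic muscle-tendon length map l_MT = a0 + a1*theta + a2*theta^2
    (theta = knee flexion in radians)."""

    a0: float
    a1: float
    a2: float

    def length(self, theta):
        th = np.asarray(theta, dtype=float)
        out = self.a0 + self.a1 * th + self.a2 * th * th
        return out if out.ndim else float(out)

    def moment_arm(self, theta):
        """Knee moment arm, m; flexion-positive (= -dl/dtheta)."""
        th = np.asarray(theta, dtype=float)
        out = -(self.a1 + 2.0 * self.a2 * th)
        return out if out.ndim else float(out)

    def scaled(self, ratio: float) -> "MuscleGeometry":
        return MuscleGeometry(self.a0 * ratio, self.a1 * ratio, self.a2 * ratio)


@dataclass
class SubjectModel:
    """Scaled skeletal + muscular model of the left knee."""

    shank_foot_mass: float
    shank_foot_com_distance: float
    shank_foot_inertia: float
    muscles: Dict[str, MuscleParams]
    geometry: Dict[str, MuscleGeometry]
    knee_range_deg: tuple = (0.0, 110.0)
    gravity: float = GRAVITY
    limit_stiffness: float = 1000.0   # N*m/rad, one-sided beyond full extension
    limit_damping: float = 2.0        # N*m*s/rad, engaged only with the limit
    anthropometry: Optional[Anthropometry] = None

    def with_passive_overrides(self, overrides: Dict[str, tuple]) -> "SubjectModel":
        """Copy of the model with (S, K) replaced for the named muscles."""
        muscles = dict(self.muscles)
        for name, (S, K) in overrides.items():
            if name not in muscles:
                raise KeyError(f"unknown muscle {name!r}")
            muscles[name] = muscles[name].with_passive(S, K)
        return replace(self, muscles=muscles)

    def with_tendon_mode(self, mode: str) -> "SubjectModel":
        muscles = {n: replace(p, tendon_mode=mode) for n, p in self.muscles.items()}
        return replace(self, muscles=muscles)


@dataclass
class Trial:
    """One recorded (or synthetic) passive-stretch trial.

    ``knee_angle_deg`` flexion-positive; the applied 6-DOF wrench is in the
    shank frame (x distal along the tibia, y perpendicular in the sagittal
    plane, z along the knee axis) at a point offset ``app_par`` along and
    ``app_perp`` perpendicular to the tibia from the knee axis.  EMG channels
    are normalised to maximum voluntary contraction.
    """

    time: np.ndarray
    knee_angle_deg: np.ndarray
    force: np.ndarray          # (n, 3) fx, fy, fz in N
    moment: np.ndarray         # (n, 3) mx, my, mz in N*m
    app_par: np.ndarray        # (n,) m
    app_perp: np.ndarray       # (n,) m
    emg: Dict[str, np.ndarray] = field(default_factory=dict)
    speed_label: str = "slow"
    group_label: str = "TD"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("time must be a 1-D array with >= 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time not strictly increasing at row {bad}")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time must be uniformly sampled")
        span = t[-1] - t[0]
        if self.speed_label == "slow" and span <= 5.0:
            warnings.warn(f"slow trial spans only {span:.2f} s (expected > 5 s)")
        if self.speed_label == "fast" and span > 1.5:
            warnings.warn(f"fast trial spans {span:.2f} s (stretch expected < 1 s)")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# Generic adult reference the subject models are scaled from.  Segment
# parameters follow standard anthropometric tables (shank+foot = 6.1% of
# body mass, COM at 60.6% and radius of gyration 73.5% of tibia length from
# the knee).  Muscle constants are lumped over each group.
REFERENCE_ANTHROPOMETRY = Anthropometry(height=1.75, mass=75.0,
                                        leg_length=0.92, tibia_length=0.43)

_SHANK_FOOT_MASS_FRAC = 0.061
_COM_FRAC = 0.606
_RGYR_FRAC = 0.735

_REF_MUSCLES = {
    "HAM": dict(F_iso_max=2600.0, l_opt=0.110, l_slack=0.330),
    "VAS": dict(F_iso_max=4500.0, l_opt=0.089, l_slack=0.137),
    "RF": dict(F_iso_max=780.0, l_opt=0.084, l_slack=0.300),
    "BFS": dict(F_iso_max=800.0, l_opt=0.173, l_slack=0.089),
    "GAS": dict(F_iso_max=1600.0, l_opt=0.055, l_slack=0.360),
}

_REF_GEOMETRY = {
    "HAM": MuscleGeometry(0.470, -0.024, -0.0060),
    "VAS": MuscleGeometry(0.200, 0.035, -0.0030),
    "RF": MuscleGeometry(0.330, 0.040, -0.0040),
    "BFS": MuscleGeometry(0.260, -0.022, -0.0040),
    "GAS": MuscleGeometry(0.405, -0.015, -0.0030),
}


def reference_model(tendon_mode: str = "elastic") -> SubjectModel:
    """The generic (unscaled) adult reference model."""
    L = REFERENCE_ANTHROPOMETRY.tibia_length
    m = _SHANK_FOOT_MASS_FRAC * REFERENCE_ANTHROPOMETRY.mass
    muscles = {
        name: MuscleParams(name=name, tendon_mode=tendon_mode, **kw)
        for name, kw in _REF_MUSCLES.items()
    }
    return SubjectModel(
        shank_foot_mass=m,
        shank_foot_com_distance=_COM_FRAC * L,
        shank_foot_inertia=m * (_RGYR_FRAC * L) ** 2,
        muscles=muscles,
        geometry=dict(_REF_GEOMETRY),
        anthropometry=REFERENCE_ANTHROPOMETRY,
    )


def scale_model(generic: SubjectModel, anthropometry: Anthropometry) -> SubjectModel:
    """Scale the generic model to a subject.

    Lengths (segment, COM, muscle l_opt, l_slack and the whole l_MT map)
    scale by the tibia-length ratio, preserving the fiber-to-tendon ratio;
    segment mass by the body-mass ratio; inertia by mass*length^2; muscle
    strength by the body-mass ratio to the 2/3 power.
    """
    ref = generic.anthropometry or REFERENCE_ANTHROPOMETRY
    len_ratio = anthropometry.tibia_length / ref.tibia_length
    mass_ratio = anthropometry.mass / ref.mass
    strength = mass_ratio ** (2.0 / 3.0)
    muscles = {
        name: replace(p,
                      F_iso_max=p.F_iso_max * strength,
                      l_opt=p.l_opt * len_ratio,
                      l_slack=p.l_slack * len_ratio)
        for name, p in generic.muscles.items()
    }
    geometry = {name: g.scaled(len_ratio) for name, g in generic.geometry.items()}
    return replace(
        generic,
        shank_foot_mass=generic.shank_foot_mass * mass_ratio,
        shank_foot_com_distance=generic.shank_foot_com_distance * len_ratio,
        shank_foot_inertia=generic.shank_foot_inertia * mass_ratio * len_ratio ** 2,
        muscles=muscles,
        geometry=geometry,
        anthropometry=anthropometry,
    )


def mt_length_and_arm(model: SubjectModel, muscle: str, knee_angle_deg):
    """Muscle-tendon length (m) and flexion-positive moment arm (m) at a
    knee angle in degrees.  Angles outside the model range are clamped with
    a warning."""
    if muscle not in model.geometry:
        raise KeyError(f"unknown muscle {muscle!r}")
    ang = np.asarray(knee_angle_deg, dtype=float)
    lo, hi = model.knee_range_deg
    if np.any(ang < lo - 1e-9) or np.any(ang > hi + 1e-9):
        warnings.warn(f"{muscle}: knee angle clamped to [{lo}, {hi}] deg")
        ang = np.clip(ang, lo, hi)
    theta = np.deg2rad(ang)
    g = model.geometry[muscle]
    return g.length(theta), g.moment_arm(theta)


def gravity_moment(model: SubjectModel, theta_rad):
    """Flexion-positive gravity moment at knee flexion theta (rad)."""
    th = np.asarray(theta_rad, dtype=float)
    out = (model.shank_foot_mass * model.gravity
           * model.shank_foot_com_distance * np.sin(th))
    return out if out.ndim else float(out)


def applied_knee_moment(force, moment, app_par, app_perp):
    """Knee-axis moment (flexion-positive) of the applied wrench.

    ``force``/``moment`` are (..., 3) in the shank frame; the lever arms are
    the measured application-point offsets along (``app_par``) and
    perpendicular to (``app_perp``) the tibia.
    """
    f = np.asarray(force, dtype=float)
    m = np.asarray(moment, dtype=float)
    out = (np.asarray(app_par, dtype=float) * f[..., 1]
           - np.asarray(app_perp, dtype=float) * f[..., 0] + m[..., 2])
    return out if out.ndim else float(out)


def limit_moment(model: SubjectModel, theta_rad, omega_rad_s=0.0):
    """One-sided hyperextension penalty engaged only beyond full extension."""
    th = np.asarray(theta_rad, dtype=float)
    om = np.asarray(omega_rad_s, dtype=float)
    engaged = th < 0.0
    out = np.where(engaged,
                   -model.limit_stiffness * th - model.limit_damping * om, 0.0)
    return out if out.ndim else float(out)


def equation_of_motion(model: SubjectModel, theta_rad, omega_rad_s,
                       muscle_moment, applied_moment=0.0):
    """Angular acceleration (rad/s^2) of the shank about the knee:
    I*thetadd = M_muscles + M_gravity + M_applied + M_limit."""
    total = (np.asarray(muscle_moment, dtype=float)
             + gravity_moment(model, theta_rad)
             + np.asarray(applied_moment, dtype=float)
             + limit_moment(model, theta_rad, omega_rad_s))
    out = total / model.shank_foot_inertia
    return out if np.ndim(out) else float(out)
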