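"""Inverse dynamics: net knee muscle moment from measured kinematics and
the applied wrench.

The net moment is everything the (unmeasured) muscles must have produced:

    M_net(t) = I * thetadd(t) - M_gravity(theta(t)) - M_applied(t)

with flexion positive throughout.  Accelerations come from zero-lag low-pass
filtering of the angle signal followed by central differences.  For fitting,
the moment-angle relation is resampled onto a uniform angle grid so dwell
time at either end of the stretch does not weight the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .limb import SubjectModel, Trial, applied_knee_moment, gravity_moment

__all__ = [
    "NetMomentCurve",
    "smooth_differentiate",
    "inverse_dynamics",
    "moment_angle_curve",
]

DEFAULT_CUTOFF_HZ = {"slow": 6.0, "fast": 20.0}
_MIN_RATE_FACTOR = 4.0  # sampling must exceed this multiple of the cutoff


@dataclass
class NetMomentCurve:
    """Paired time / knee state / net internal muscle moment series.

    The angle (and its derivative) are the low-pass-filtered versions used
    for the acceleration estimate, so angle, velocity and moment stay
    mutually consistent.
    """

    time: np.ndarray
    knee_angle_deg: np.ndarray
    net_moment: np.ndarray  # N*m, flexor positive
    knee_velocity_deg_s: np.ndarray = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "angle_deg": self.knee_angle_deg,
            "moment_Nm": self.net_moment,
            "omega_deg_s": (np.zeros_like(self.time)
                            if self.knee_velocity_deg_s is None
                            else self.knee_velocity_deg_s),
        })


def smooth_differentiate(signal, dt, cutoff_hz=None):
    """First and second time derivatives of a uniformly sampled signal.

    A zero-lag 4th-order (2nd-order applied forward and backward)
    Butterworth low-pass at ``cutoff_hz`` precedes central differencing;
    pass ``cutoff_hz=None`` to differentiate the raw signal.
    """
    x = np.asarray(signal, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cutoff_hz is not None:
        nyq = 0.5 / dt
        if cutoff_hz >= nyq:
            raise ValueError(
                f"cutoff {cutoff_hz} Hz >= Nyquist {nyq:.1f} Hz; sample at "
                f"more than {_MIN_RATE_FACTOR * cutoff_hz:.0f} Hz")
        if nyq < _MIN_RATE_FACTOR * cutoff_hz / 2:
            raise ValueError(
                f"sampling rate {1/dt:.1f} Hz too low for a {cutoff_hz} Hz "
                f"cutoff; need >= {2 * _MIN_RATE_FACTOR * cutoff_hz:.0f} Hz")
        b, a = butter(2, cutoff_hz / nyq)
        x = filtfilt(b, a, x)
    d1 = np.gradient(x, dt)
    d2 = np.gradient(d1, dt)
    return d1, d2


def lowpass(signal, dt, cutoff_hz):
    """Zero-lag Butterworth low-pass (the same filter the derivatives use)."""
    nyq = 0.5 / dt
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def inverse_dynamics(model: SubjectModel, trial: Trial,
                     cutoff_hz=None) -> NetMomentCurve:
    """Net knee muscle moment time series for one trial.

    ``cutoff_hz`` defaults per speed label (6 Hz slow, 20 Hz fast).
    """
    if cutoff_hz is None:
        cutoff_hz = DEFAULT_CUTOFF_HZ.get(trial.speed_label, 6.0)
    theta = np.deg2rad(trial.knee_angle_deg)
    thetad, thetadd = smooth_differentiate(theta, trial.dt, cutoff_hz)
    theta_f = lowpass(theta, trial.dt, cutoff_hz) if cutoff_hz else theta
    m_grav = gravity_moment(model, theta_f)
    m_app = applied_knee_moment(trial.force, trial.moment,
                                trial.app_par, trial.app_perp)
    net = model.shank_foot_inertia * thetadd - m_grav - m_app
    return NetMomentCurve(trial.time.copy(), np.rad2deg(theta_f), net,
                          np.rad2deg(thetad))


def moment_angle_curve(curve: NetMomentCurve, bin_deg: float = 1.0,
                       trim_s: float = 0.0) -> pd.DataFrame:
    """Resample a net-moment curve onto a uniform knee-angle grid.

    Samples are averaged within ``bin_deg`` bins (bin centres reported);
    ``trim_s`` drops that much data at each end of the record, where filter
    edge effects live.  Returns a DataFrame with ``angle_deg``/``moment_Nm``
    sorted by angle.
    """
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    t, ang, mom = curve.time, curve.knee_angle_deg, curve.net_moment
    omega = (np.zeros_like(t) if curve.knee_velocity_deg_s is None
             else curve.knee_velocity_deg_s)
    keep = (t >= t[0] + trim_s) & (t <= t[-1] - trim_s)
    ang, mom, omega = ang[keep], mom[keep], omega[keep]
    bins = np.round(ang / bin_deg).astype(int)
    df = pd.DataFrame({"bin": bins, "moment_Nm": mom, "omega_deg_s": omega})
    grouped = df.groupby("bin").mean()
    return pd.DataFrame({
        "angle_deg": grouped.index.to_numpy(dtype=float) * bin_deg,
        "moment_Nm": grouped["moment_Nm"].to_numpy(),
        "omega_deg_s": grouped["omega_deg_s"].to_numpy(),
    }).sort_values("angle_deg", ignore_index=True)
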