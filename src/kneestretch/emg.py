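"""EMG onset detection, background-activity screening, and reflex-threshold
estimation.

Onset detection approximates a generalized-likelihood-ratio changepoint
test for a variance increase: the signal is whitened by the baseline
standard deviation, and a sliding-window log-likelihood statistic

    g_t = (W / 2) * (r_t - 1 - ln r_t),   r_t = windowed mean of (x/sigma0)^2

is evaluated for r_t > 1.  Onset is declared at the first crossing of a
threshold ``h`` sustained for a minimum duration, then refined by
backtracking to the first clearly supra-baseline sample inside the window.

The reflex threshold T is the muscle-tendon lengthening velocity of the
hamstrings 30 ms before EMG onset (fiber velocity is taken equal to
muscle-tendon velocity, reasonable at the low forces of passive stretch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .invdyn import smooth_differentiate
from .limb import SubjectModel, Trial, mt_length_and_arm

__all__ = [
    "OnsetConfig",
    "OnsetResult",
    "ThresholdEstimate",
    "detect_onset",
    "estimate_threshold",
    "background_activity_check",
]


@dataclass(frozen=True)
class OnsetConfig:
    window_s: float = 0.020        # sliding statistic window
    baseline_s: float = 0.100      # initial segment for sigma0
    threshold: float = 10.0        # GLR statistic threshold h
    min_duration_s: float = 0.010  # crossing must be sustained this long
    backtrack_z2: float = 9.0      # (x/sigma0)^2 marking supra-baseline


@dataclass
class OnsetResult:
    onset_time: Optional[float]
    statistic: np.ndarray
    config: OnsetConfig = field(default_factory=OnsetConfig)


@dataclass
class ThresholdEstimate:
    T: float                 # MT lengthening velocity, m/s
    onset_time: float
    flagged: bool = False    # onset - 30 ms fell before the record


def detect_onset(emg, dt, config: OnsetConfig | None = None) -> OnsetResult:
    """Detect EMG burst onset in a raw (signed) channel.

    Returns an :class:`OnsetResult` with ``onset_time=None`` when no
    sustained variance increase is found.
    """
    cfg = config or OnsetConfig()
    x = np.asarray(emg, dtype=float)
    w = max(int(round(cfg.window_s / dt)), 2)
    nb = max(int(round(cfg.baseline_s / dt)), 2 * w)
    if len(x) < nb + w:
        raise ValueError(
            f"channel of {len(x)} samples shorter than baseline+window "
            f"({nb + w} samples)")
    sigma0 = np.std(x[:nb])
    if sigma0 == 0.0:
        return OnsetResult(None, np.zeros(len(x)), cfg)
    z2 = (x / sigma0) ** 2
    # causal sliding mean of z2 over the window (expanding at the start)
    c = np.concatenate(([0.0], np.cumsum(z2)))
    idx = np.arange(len(x))
    lo_idx = np.maximum(idx - w + 1, 0)
    r = np.maximum((c[idx + 1] - c[lo_idx]) / (idx + 1 - lo_idx), 1e-12)
    g = np.where(r > 1.0, 0.5 * w * (r - 1.0 - np.log(r)), 0.0)
    above = g > cfg.threshold
    need = max(int(round(cfg.min_duration_s / dt)), 1)
    # first index where `above` holds for `need` consecutive samples
    run = 0
    t_cross = None
    for i in range(nb, len(x)):
        run = run + 1 if above[i] else 0
        if run >= need:
            t_cross = i - need + 1
            break
    if t_cross is None:
        return OnsetResult(None, g, cfg)
    # backtrack: earliest clearly supra-baseline sample within one window
    lo = max(t_cross - w, 0)
    seg = np.nonzero(z2[lo:t_cross + 1] > cfg.backtrack_z2)[0]
    idx = lo + int(seg[0]) if len(seg) else t_cross - w // 2
    return OnsetResult(float(idx * dt), g, cfg)


def estimate_threshold(trial: Trial, model: SubjectModel, onset: OnsetResult,
                       delay_s: float = 0.030, muscle: str = "HAM",
                       cutoff_hz: float = 20.0) -> ThresholdEstimate:
    """Reflex threshold velocity from a fast trial with detected EMG onset.

    T is the smoothed d(l_MT)/dt of the target muscle evaluated ``delay_s``
    (default 30 ms) before onset; if that instant precedes the record the
    first sample is used and the estimate flagged.
    """
    if onset.onset_time is None:
        raise ValueError("cannot estimate threshold without an EMG onset")
    l_mt, _ = mt_length_and_arm(model, muscle, trial.knee_angle_deg)
    v_mt, _ = smooth_differentiate(l_mt, trial.dt, cutoff_hz)
    t_eval = onset.onset_time - delay_s
    flagged = t_eval < trial.time[0]
    t_eval = max(t_eval, float(trial.time[0]))
    T = float(np.interp(t_eval, trial.time, v_mt))
    return ThresholdEstimate(T=T, onset_time=float(onset.onset_time),
                             flagged=bool(flagged))


def background_activity_check(slow_emg, mvc_rms: float):
    """Screen a slow-stretch EMG channel for background activation.

    Returns ``(passed, ratio)`` where ratio = RMS(slow EMG)/RMS(MVC EMG);
    the check fails when the ratio strictly exceeds 10% ("higher than"),
    the exclusion rule for subjects who were not relaxed.
    """
    if mvc_rms <= 0:
        raise ValueError("MVC reference RMS must be positive")
    x = np.asarray(slow_emg, dtype=float)
    ratio = float(np.sqrt(np.mean(x ** 2)) / mvc_rms)
    # strict "higher than 10%" rule; epsilon keeps the boundary case stable
    return ratio <= 0.10 * (1.0 + 1e-12), ratio
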