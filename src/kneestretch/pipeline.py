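"""End-to-end subject assessment: the full analysis chain applied to one
subject's slow and fast trials.

Chain: background-EMG screening -> inverse dynamics of the slow stretch ->
passive (S, K) fitting -> EMG onset and reflex-threshold estimation from
the fast stretch -> forward-dynamic gain sweep -> RMS evaluation and
optimal-gain selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .emg import (OnsetResult, ThresholdEstimate, background_activity_check,
                  detect_onset, estimate_threshold)
from .evaluate import EvalResult, PhaseWindows, evaluate_gain_sweep
from .invdyn import inverse_dynamics, moment_angle_curve
from .limb import Anthropometry, SubjectModel, Trial, reference_model, scale_model
from .passive_fit import FitResult, fit_passive_params
from .reflex import GAIN_GRID, ReflexParams
from .simulate import SimConfig, run_gain_sweep

__all__ = ["SubjectAssessment", "model_from_trial", "assess_subject"]


@dataclass
class SubjectAssessment:
    subject_id: str
    fit: FitResult
    onset: Optional[OnsetResult]
    threshold: Optional[ThresholdEstimate]
    evaluation: EvalResult
    background_ok: bool
    background_ratio: float
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "fit": self.fit.to_dict(),
            "onset_time_s": None if self.onset is None else self.onset.onset_time,
            "threshold_m_s": None if self.threshold is None else self.threshold.T,
            "per_gain_rms_stretch_deg": self.evaluation.per_gain_stretch,
            "per_gain_rms_stretch_hold_deg": self.evaluation.per_gain_stretch_hold,
            "optimal_gain": self.evaluation.optimal_gain,
            "background_ratio": self.background_ratio,
            "notes": self.notes,
        }


def model_from_trial(trial: Trial) -> SubjectModel:
    """Build the scaled subject model from a trial's metadata sidecar."""
    meta = trial.meta
    if "anthropometry" not in meta:
        raise ValueError("trial metadata lacks anthropometry; cannot scale")
    anthro = Anthropometry(**meta["anthropometry"])
    return scale_model(reference_model(meta.get("tendon_mode", "elastic")),
                       anthro)


def assess_subject(slow: Trial, fast: Trial,
                   model: Optional[SubjectModel] = None,
                   sim_config: Optional[SimConfig] = None,
                   curve_trim_s: float = 0.25) -> SubjectAssessment:
    """Run the whole assessment for one subject.

    The passive fit uses the slow trial only; the reflex threshold and gain
    sweep use the fast trial; evaluation windows follow the group label
    (stretch phase until 0.4 s in CP, 0.6 s in TD).
    """
    notes = []
    model = model or model_from_trial(slow)
    mvc = float(slow.meta.get("mvc_rms", 1.0))
    bg_ok, bg_ratio = True, 0.0
    if "ham" in slow.emg:
        bg_ok, bg_ratio = background_activity_check(slow.emg["ham"], mvc)
        if not bg_ok:
            notes.append(f"background EMG {bg_ratio:.1%} of MVC exceeds 10%; "
                         "subject would be excluded")

    curve = moment_angle_curve(inverse_dynamics(model, slow),
                               trim_s=curve_trim_s)
    fit = fit_passive_params(model, curve)

    onset = threshold = None
    if "ham" in fast.emg:
        onset = detect_onset(fast.emg["ham"], fast.dt)
        if onset.onset_time is not None:
            threshold = estimate_threshold(fast, model, onset)
        else:
            notes.append("no EMG onset in fast trial; reflex disabled in the "
                         "sweep (gain irrelevant, optimal gain 0)")
    base = ReflexParams(G=0.0, T=threshold.T, enabled=True) if threshold \
        else ReflexParams(G=0.0, T=0.0, enabled=False)
    sweep = run_gain_sweep(model, fast, fit, base, sim_config, GAIN_GRID)
    evaluation = evaluate_gain_sweep(sweep, fast.time, fast.knee_angle_deg,
                                     PhaseWindows.for_group(fast.group_label))
    return SubjectAssessment(
        subject_id=str(slow.meta.get("subject_id", "unknown")),
        fit=fit, onset=onset, threshold=threshold, evaluation=evaluation,
        background_ok=bg_ok, background_ratio=bg_ratio, notes=notes)
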