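"""Forward dynamics: equilibrium, determinism, convergence, reflex timing."""

import numpy as np
import pytest
from scipy.optimize import brentq

from kneestretch.limb import Trial, gravity_moment
from kneestretch.passive_fit import muscle_moment_sum
from kneestretch.reflex import GAIN_GRID, ReflexParams
from kneestretch.simulate import SimConfig, forward_simulate, run_gain_sweep


def _zero_wrench_trial(angle0, duration=1.0, dt=0.01, speed="fast"):
    n = int(round(duration / dt)) + 1
    return Trial(time=dt * np.arange(n),
                 knee_angle_deg=np.full(n, float(angle0)),
                 force=np.zeros((n, 3)), moment=np.zeros((n, 3)),
                 app_par=np.zeros(n), app_perp=np.zeros(n),
                 speed_label=speed, group_label="CP")


def _equilibrium_angle(model):
    def total(angle_deg):
        return muscle_moment_sum(model, float(angle_deg)) + gravity_moment(
            model, np.deg2rad(angle_deg))
    return brentq(total, 30.0, 109.0, xtol=1e-10)


def test_knee_rests_at_passive_equilibrium(child_model):
    """Released at its passive equilibrium with no wrench, the knee stays
    put (and above the hyperextension tolerance)."""
    eq = _equilibrium_angle(child_model)
    sim = forward_simulate(child_model, _zero_wrench_trial(eq),
                           config=SimConfig(duration=1.0))
    assert np.max(np.abs(sim.knee_angle_deg - eq)) < 0.1
    assert sim.knee_angle_deg.min() >= -0.5


def test_elastic_tendon_equilibrium_hold(child_model):
    model = child_model.with_tendon_mode("elastic")
    eq = _equilibrium_angle(model)  # equilibrium of the elastic model itself
    sim = forward_simulate(model, _zero_wrench_trial(eq),
                           config=SimConfig(duration=1.0))
    assert sim.diagnostics["tendon_mode"] == "elastic"
    assert np.max(np.abs(sim.knee_angle_deg - eq)) < 0.2
    assert np.all(sim.activation >= 0.01 - 1e-12)
    assert np.all(sim.activation <= 1.0)


def test_zero_gain_equals_disabled_controller(cp_truth, fast_trial_clean):
    model = cp_truth.build_model()
    a = forward_simulate(model, fast_trial_clean, None, None)
    b = forward_simulate(model, fast_trial_clean, None,
                         ReflexParams(G=0.0, T=0.08))
    assert np.array_equal(a.knee_angle_deg, b.knee_angle_deg)
    assert np.array_equal(a.activation, b.activation)


def test_resimulation_reproduces_measurement(cp_truth, fast_trial_clean):
    """Simulating a synthetic fast trial from its own recorded inputs with
    the true parameters reproduces the measured knee angle."""
    model = cp_truth.build_model()
    sim = forward_simulate(model, fast_trial_clean, None, cp_truth.reflex)
    resim = np.interp(fast_trial_clean.time, sim.time, sim.knee_angle_deg)
    rms = np.sqrt(np.mean((resim - fast_trial_clean.knee_angle_deg) ** 2))
    assert rms < 0.1


def test_step_halving_convergence(cp_truth, slow_trial_clean,
                                  fast_trial_clean):
    """Halving the step leaves the final angle unchanged to < 0.05 deg for
    the smooth (no-reflex, limit-free) dynamics; with the reflex the
    piecewise law is discontinuous at threshold, so the switch is resolved
    to one step and convergence there is first order (looser bound)."""
    model = cp_truth.build_model()
    a1 = forward_simulate(model, slow_trial_clean, None, None,
                          SimConfig(dt=0.001, duration=2.5))
    a2 = forward_simulate(model, slow_trial_clean, None, None,
                          SimConfig(dt=0.0005, duration=2.5))
    assert a1.diagnostics["limit_engaged_steps"] == 0
    assert abs(a1.knee_angle_deg[-1] - a2.knee_angle_deg[-1]) < 0.05
    s1 = forward_simulate(model, fast_trial_clean, None, cp_truth.reflex,
                          SimConfig(dt=0.001))
    s2 = forward_simulate(model, fast_trial_clean, None, cp_truth.reflex,
                          SimConfig(dt=0.0005))
    assert abs(s1.knee_angle_deg[-1] - s2.knee_angle_deg[-1]) < 0.25


def test_reflex_burst_trails_crossing_by_delay(fast_sweep):
    """Excitation onset follows the first supra-threshold fiber-velocity
    sample by exactly the 30 ms reflex delay (within one step)."""
    for g in (1.0, 2.0, 4.0):
        sim = fast_sweep[g]
        ih = sim.muscle_index("HAM")
        dt = sim.diagnostics["dt"]
        cross = sim.time[np.nonzero(sim.v_fiber[:, ih] > 0.08)[0][0]]
        exc_on = sim.time[np.nonzero(sim.excitation[:, ih] > 0)[0][0]]
        assert exc_on - cross == pytest.approx(0.030, abs=dt + 1e-12)


def test_peak_fiber_state_non_increasing_in_gain(fast_sweep):
    """A stronger reflex arrests the stretch earlier: peak hamstrings fiber
    length and lengthening velocity fall (or hold) as G rises."""
    ih = fast_sweep[0.0].muscle_index("HAM")
    peak_l = [fast_sweep[g].l_fiber_norm[:, ih].max() for g in GAIN_GRID]
    peak_v = [fast_sweep[g].v_fiber[:, ih].max() for g in GAIN_GRID]
    assert np.all(np.diff(peak_l) <= 1e-9)
    assert np.all(np.diff(peak_v) <= 1e-9)


def test_end_range_angle_non_decreasing_in_gain(fast_sweep):
    mins = [fast_sweep[g].knee_angle_deg.min() for g in GAIN_GRID]
    assert np.all(np.diff(mins) >= -1e-9)


def test_gain_runs_share_pre_onset_trajectory(fast_sweep):
    """All gains coincide until threshold crossing + delay."""
    ih = fast_sweep[4.0].muscle_index("HAM")
    first_exc = np.nonzero(fast_sweep[4.0].excitation[:, ih] > 0)[0][0]
    for g in (0.0, 1.0, 2.0):
        assert np.allclose(
            fast_sweep[g].knee_angle_deg[:first_exc],
            fast_sweep[4.0].knee_angle_deg[:first_exc], atol=1e-9)


def test_gain_sweep_contains_all_gains(fast_sweep):
    assert set(fast_sweep) == set(GAIN_GRID)
    df = fast_sweep[2.0].to_dataframe()
    assert {"knee_angle_deg", "act_ham", "vf_ham_m_s"} <= set(df.columns)
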