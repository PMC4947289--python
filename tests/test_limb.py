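"""Skeletal model: scaling arithmetic, geometry consistency, dynamics."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from kneestretch.limb import (Anthropometry, REFERENCE_ANTHROPOMETRY, Trial,
                              equation_of_motion, gravity_moment,
                              applied_knee_moment, mt_length_and_arm,
                              reference_model, scale_model)


def test_anthropometry_validation():
    with pytest.raises(ValueError):
        Anthropometry(height=1.5, mass=-3.0, leg_length=0.7, tibia_length=0.35)
    with pytest.raises(ValueError):
        Anthropometry(height=1.5, mass=30.0, leg_length=0.3, tibia_length=0.35)


def test_scaling_identity_at_reference():
    ref = reference_model()
    scaled = scale_model(ref, REFERENCE_ANTHROPOMETRY)
    assert scaled.shank_foot_mass == pytest.approx(ref.shank_foot_mass)
    assert scaled.shank_foot_inertia == pytest.approx(ref.shank_foot_inertia)
    for name in ref.muscles:
        assert scaled.muscles[name].F_iso_max == pytest.approx(
            ref.muscles[name].F_iso_max)
        assert scaled.geometry[name].a0 == pytest.approx(ref.geometry[name].a0)


def test_strength_scales_with_mass_to_two_thirds():
    ref = reference_model()
    a = dataclasses.replace(REFERENCE_ANTHROPOMETRY,
                            mass=8.0 * REFERENCE_ANTHROPOMETRY.mass)
    scaled = scale_model(ref, a)
    for name in ref.muscles:
        assert scaled.muscles[name].F_iso_max == pytest.approx(
            4.0 * ref.muscles[name].F_iso_max)  # 8^(2/3) = 4


def test_length_and_strength_ratios_combine():
    ref = reference_model()
    a = Anthropometry(height=REFERENCE_ANTHROPOMETRY.height * 0.9,
                      mass=REFERENCE_ANTHROPOMETRY.mass * 0.8,
                      leg_length=REFERENCE_ANTHROPOMETRY.leg_length * 0.9,
                      tibia_length=REFERENCE_ANTHROPOMETRY.tibia_length * 0.9)
    scaled = scale_model(ref, a)
    l_ref, _ = mt_length_and_arm(ref, "HAM", 30.0)
    l_scaled, _ = mt_length_and_arm(scaled, "HAM", 30.0)
    assert l_scaled == pytest.approx(0.9 * l_ref, rel=1e-12)
    assert scaled.muscles["HAM"].F_iso_max == pytest.approx(
        0.8 ** (2 / 3) * ref.muscles["HAM"].F_iso_max, rel=1e-12)
    # fiber-to-tendon ratio preserved
    m0, m1 = ref.muscles["HAM"], scaled.muscles["HAM"]
    assert m1.l_opt / m1.l_slack == pytest.approx(m0.l_opt / m0.l_slack)


def test_moment_arm_matches_length_derivative(child_model):
    """Virtual-work consistency: r = -dl_MT/dtheta for every muscle."""
    angles = np.linspace(1.0, 109.0, 50)
    h = 1e-4  # rad
    for name in child_model.muscles:
        l_mt, arm = mt_length_and_arm(child_model, name, angles)
        lp = child_model.geometry[name].length(np.deg2rad(angles) + h)
        lm = child_model.geometry[name].length(np.deg2rad(angles) - h)
        arm_fd = -(lp - lm) / (2 * h)
        assert np.allclose(arm, arm_fd, atol=1e-6)


def test_flexor_extensor_arm_signs(child_model):
    angles = np.linspace(0.0, 110.0, 40)
    for name, sign in (("HAM", 1), ("BFS", 1), ("GAS", 1), ("VAS", -1),
                       ("RF", -1)):
        _, arm = mt_length_and_arm(child_model, name, angles)
        assert np.all(sign * arm > 0), name


def test_hamstrings_longest_at_full_extension(child_model):
    angles = np.linspace(0.0, 110.0, 111)
    l_mt, _ = mt_length_and_arm(child_model, "HAM", angles)
    assert np.argmax(l_mt) == 0


def test_angle_clamp_warns(child_model):
    with pytest.warns(UserWarning):
        mt_length_and_arm(child_model, "HAM", 150.0)
    with pytest.raises(KeyError):
        mt_length_and_arm(child_model, "SOL", 30.0)


def test_equation_of_motion_trivial_cases(child_model):
    # upright shank, no muscles, no wrench: unstable equilibrium, zero accel
    assert equation_of_motion(child_model, 0.0, 0.0, 0.0, 0.0) == pytest.approx(0.0)
    # pure applied moment: theta_dd = M / I (at theta = 0 gravity vanishes)
    M = 2.5
    assert equation_of_motion(child_model, 0.0, 0.0, 0.0, M) == pytest.approx(
        M / child_model.shank_foot_inertia)


def test_applied_wrench_moment_composition():
    force = np.array([3.0, -10.0, 0.0])
    moment = np.array([0.0, 0.0, 1.5])
    m = applied_knee_moment(force, moment, app_par=0.3, app_perp=0.05)
    assert m == pytest.approx(0.3 * -10.0 - 0.05 * 3.0 + 1.5)


def test_pendulum_frequency_matches_closed_form(child_model):
    """Small oscillation about the hanging position (theta = pi) has
    frequency sqrt(mgd/I)/2pi — muscles removed, gravity only."""
    m = child_model
    mgd = m.shank_foot_mass * m.gravity * m.shank_foot_com_distance
    f_expected = np.sqrt(mgd / m.shank_foot_inertia) / (2 * np.pi)

    def rhs(t, y):
        return [y[1], equation_of_motion(m, y[0], y[1], 0.0, 0.0)]

    theta0 = np.pi - 0.05
    sol = solve_ivp(rhs, (0, 4.0), [theta0, 0.0], rtol=1e-10, atol=1e-12,
                    dense_output=True)
    t = np.linspace(0, 4.0, 8001)
    th = sol.sol(t)[0]
    # period from zero crossings of (theta - pi)
    s = np.sign(th - np.pi)
    crossings = t[np.nonzero(np.diff(s))[0]]
    period = 2 * np.mean(np.diff(crossings))
    assert 1.0 / period == pytest.approx(f_expected, rel=0.01)


def test_free_swing_conserves_energy(child_model):
    """With all muscles removed, the swinging shank conserves mechanical
    energy to integrator tolerance."""
    m = child_model
    mgd = m.shank_foot_mass * m.gravity * m.shank_foot_com_distance

    def rhs(t, y):
        return [y[1], equation_of_motion(m, y[0], y[1], 0.0, 0.0)]

    sol = solve_ivp(rhs, (0, 3.0), [np.pi / 2, 0.0], rtol=1e-10, atol=1e-12)
    E = 0.5 * m.shank_foot_inertia * sol.y[1] ** 2 + mgd * np.cos(sol.y[0])
    assert np.max(np.abs(E - E[0])) < 1e-6 * mgd  # mgd sets the energy scale


def test_trial_time_validation():
    n = 10
    t = np.linspace(0, 1, n)
    kw = dict(knee_angle_deg=np.zeros(n), force=np.zeros((n, 3)),
              moment=np.zeros((n, 3)), app_par=np.zeros(n),
              app_perp=np.zeros(n), speed_label="fast")
    Trial(time=t, **kw)  # valid
    bad = t.copy()
    bad[4] = bad[3]
    with pytest.raises(ValueError, match="row"):
        Trial(time=bad, **kw)
    with pytest.warns(UserWarning, match="slow"):
        Trial(time=t, **{**kw, "speed_label": "slow"})
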