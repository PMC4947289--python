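"""Hill/Thelen curve closed forms, activation dynamics, and tendon
equilibrium."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneestretch.muscle import (MuscleParams, activation_dynamics_step,
                                active_force_length_norm, force_velocity_inverse,
                                force_velocity_norm, muscle_force,
                                passive_force_norm, solve_fiber_equilibrium,
                                tendon_force_norm, tendon_strain_from_force)


@pytest.mark.parametrize("L, S, K, expected", [
    (1.0, 0.6, 4.0, 0.0),                                # slack at optimal
    (1.6, 0.6, 4.0, 1.0),                                # strain S by definition
    (1.3, 0.6, 4.0, (np.e ** 2 - 1) / (np.e ** 4 - 1)),  # closed form
    (0.7, 0.6, 4.0, 0.0),                                # clamped below optimal
])
def test_passive_force_closed_form(L, S, K, expected):
    assert passive_force_norm(L, S, K) == pytest.approx(expected, abs=1e-12)


@given(S=st.floats(0.1, 5.0), K=st.floats(0.5, 20.0))
def test_passive_force_is_one_at_strain_S(S, K):
    """F_pe(1+S) = 1 exactly: S is defined as the strain at max isometric
    force."""
    assert passive_force_norm(1.0 + S, S, K) == pytest.approx(1.0, abs=1e-12)


@given(S=st.floats(0.2, 3.0), K=st.floats(1.0, 15.0))
def test_passive_force_monotone_in_length(S, K):
    L = np.linspace(0.5, 2.5, 200)
    f = passive_force_norm(L, S, K)
    assert np.all(np.diff(f) >= 0)
    assert np.all(f >= 0)


def test_passive_force_sharper_toe_with_larger_K():
    # below strain S a larger K suppresses the toe; the curves cross at 1+S
    L = 1.2
    f = [passive_force_norm(L, 0.6, K) for K in (2.0, 4.0, 8.0)]
    assert f[0] > f[1] > f[2]


def test_passive_force_rejects_nonpositive_parameters():
    with pytest.raises(ValueError):
        passive_force_norm(1.2, -0.1, 4.0)
    with pytest.raises(ValueError):
        passive_force_norm(1.2, 0.6, 0.0)


@pytest.mark.parametrize("L, expected", [
    (1.0, 1.0),
    (1.3, np.exp(-0.2)),
    (0.7, np.exp(-0.2)),  # symmetric about optimal
])
def test_active_force_length(L, expected):
    assert active_force_length_norm(L, 0.45) == pytest.approx(expected, rel=1e-12)


def test_force_velocity_limits():
    assert force_velocity_norm(0.0) == pytest.approx(1.0)
    assert force_velocity_norm(-10.0, v_max=10.0) == 0.0
    assert force_velocity_norm(-15.0, v_max=10.0) == 0.0
    ecc = force_velocity_norm(5.0, 1.0, 10.0)
    assert 1.0 < ecc <= 1.4
    # recorded value of the chosen eccentric branch at +0.5 v_max
    assert ecc == pytest.approx((1.0 + 0.5 * 1.4 / 0.08) / (1.0 + 0.5 / 0.08),
                                rel=1e-12)


@given(u=st.floats(-0.95, 2.0))
def test_force_velocity_inverse_roundtrip(u):
    f = force_velocity_norm(u * 10.0, v_max=10.0)
    if 1e-6 < f < 1.39:  # away from the clamps the map is a bijection
        u_back = force_velocity_inverse(f, v_max=10.0) / 10.0
        assert u_back == pytest.approx(u, abs=1e-9)


def test_tendon_force_anchors():
    assert tendon_force_norm(-0.01) == 0.0
    assert tendon_force_norm(0.0) == 0.0
    assert tendon_force_norm(0.033) == pytest.approx(1.0, abs=1e-12)
    # toe-region value against the closed-form expression
    eps0, eps = 0.033, 0.01
    eps_toe = 0.609 * eps0
    expected = 0.33 * np.expm1(3.0 * eps / eps_toe) / np.expm1(3.0)
    assert tendon_force_norm(eps) == pytest.approx(expected, rel=1e-12)


@given(eps=st.floats(0.001, 0.08))
def test_tendon_strain_inverse_roundtrip(eps):
    f = tendon_force_norm(eps)
    assert tendon_strain_from_force(f) == pytest.approx(eps, abs=1e-12)


def test_activation_dynamics_fixed_point_and_saturation():
    assert activation_dynamics_step(0.5, 0.5, 0.01) == pytest.approx(0.5)
    a = 0.01
    for _ in range(100):
        a = activation_dynamics_step(1.0, a, 0.01)
    assert a == pytest.approx(1.0, abs=1e-6)


def test_activation_dynamics_matches_analytic_exponential():
    # constant excitation: a(t) = u + (a0-u) exp(-t/tau)
    tau, a0, u = 0.01, 0.01, 0.5
    a = activation_dynamics_step(u, a0, tau, tau_act=tau)
    assert a == pytest.approx(u + (a0 - u) * np.exp(-1.0), rel=1e-12)


def test_activation_dynamics_floor_and_dt_validation():
    a = activation_dynamics_step(0.0, 0.3, 1.0, tau_deact=0.04, floor=0.01)
    assert a >= 0.01
    with pytest.raises(ValueError):
        activation_dynamics_step(0.5, 0.5, 0.0)


def _ham(mode="rigid", **kw):
    base = dict(name="HAM", F_iso_max=2600.0, l_opt=0.11, l_slack=0.33,
                tendon_mode=mode)
    base.update(kw)
    return MuscleParams(**base)


def test_muscle_force_default_activation_at_optimal_length():
    p = _ham("rigid")
    f, state = muscle_force(p, p.l_slack + p.l_opt, activation=0.01)
    assert f == pytest.approx(0.01 * p.F_iso_max, rel=1e-9)
    assert state.l_fiber_norm == pytest.approx(1.0)


def test_muscle_force_passive_normalisation():
    # a = 0 at fiber strain S: the passive element alone carries F_iso_max
    p = _ham("rigid")
    f, _ = muscle_force(p, p.l_slack + p.l_opt * (1 + p.S), activation=0.0)
    assert f == pytest.approx(p.F_iso_max, rel=1e-9)


def test_rigid_and_stiff_elastic_tendon_agree():
    """Elastic-tendon equilibrium converges on the rigid solution as the
    tendon is made stiff."""
    rigid = _ham("rigid")
    stiff = _ham("elastic", tendon_strain_iso=1e-4)
    for l_mt in (0.44, 0.455, 0.47):
        f_r, _ = muscle_force(rigid, l_mt, activation=0.01)
        f_e, _ = muscle_force(stiff, l_mt, activation=0.01)
        assert abs(f_e - f_r) < 1e-3 * rigid.F_iso_max


def test_elastic_equilibrium_residual_below_1e8_newton():
    p = _ham("elastic")
    l_mt = np.linspace(0.40, 0.49, 25)
    l_norm, force = solve_fiber_equilibrium(p, l_mt, 0.05)
    eps = (l_mt - l_norm * p.l_opt) / p.l_slack - 1.0
    muscle_side = p.F_iso_max * (
        0.05 * active_force_length_norm(l_norm, p.gamma)
        + passive_force_norm(l_norm, p.S, p.K))
    tendon_side = p.F_iso_max * tendon_force_norm(eps, p.tendon_strain_iso)
    assert np.all(np.abs(muscle_side - tendon_side) < 1e-8)
    assert np.allclose(force, tendon_side)


def test_muscle_params_validation():
    with pytest.raises(ValueError):
        _ham(S=-1.0)
    with pytest.raises(ValueError):
        _ham(F_iso_max=0.0)
    with pytest.raises(ValueError):
        _ham(a_default=0.0)
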