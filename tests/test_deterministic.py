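"""Deterministic vector field, fixed points, linearization, landmarks."""

import numpy as np
import pytest

from stochhh import (
    DeterministicState,
    HHParameters,
    deterministic_rhs,
    find_fixed_point,
    find_hopf,
    integrate,
    linearize,
)
from stochhh.deterministic import jacobian, spiking_initial_state, sustained_spiking


def test_rhs_leak_only(params):
    # all voltage-gated conductances off and V at the leak reversal
    st = DeterministicState(V=params.VL, m=0.0, h=0.5, n=0.0)
    d = deterministic_rhs(st, 3.0, params)
    assert d[0] == pytest.approx(3.0 / params.C)


def test_rhs_gating_equilibrium(params):
    from stochhh import gate_rates

    V = -58.0
    r = gate_rates(V)
    st = DeterministicState(V=V, m=r.alpha_m / (r.alpha_m + r.beta_m), h=0.3, n=0.4)
    assert deterministic_rhs(st, 0.0, params)[1] == pytest.approx(0.0, abs=1e-14)


def test_fixed_point_residual(params):
    fp = find_fixed_point(0.0, params)
    assert np.max(np.abs(deterministic_rhs(fp, 0.0, params))) < 1e-10


def test_fixed_point_voltage_monotone_in_current(params):
    Vs = [find_fixed_point(I, params).V for I in np.arange(0.0, 12.01, 0.5)]
    assert np.all(np.diff(Vs) > 0)


def test_jacobian_matches_finite_differences(params):
    I = 5.0
    fp = find_fixed_point(I, params)
    J = jacobian(fp, I, params)
    y0 = fp.as_array()
    eps = 1e-6
    for j in range(4):
        e = np.zeros(4)
        e[j] = eps
        hi = deterministic_rhs(DeterministicState(*(y0 + e)), I, params)
        lo = deterministic_rhs(DeterministicState(*(y0 - e)), I, params)
        assert np.allclose(J[:, j], (hi - lo) / (2 * eps), rtol=2e-5, atol=1e-7)


def test_eigenvalue_sum_equals_trace(params):
    for I in (0.0, 5.0, 9.0):
        L = linearize(I, params)
        fp = L.fixed_point
        tr = np.trace(jacobian(fp, I, params))
        assert np.sum(L.eigenvalues).real == pytest.approx(tr, rel=1e-8)
        assert np.sum(L.eigenvalues).imag == pytest.approx(0.0, abs=1e-10)


def test_linearization_reference_eigenvalues(params):
    # fixed-point eigenstructure at I = 5 and I = 9, two significant figures
    L5 = linearize(5.0, params)
    assert L5.lambda_re == pytest.approx(-0.097, abs=0.005)
    assert L5.omega == pytest.approx(0.521, abs=0.005)
    assert L5.ev_slow == pytest.approx(-0.129, abs=0.005)
    assert L5.ev_fast == pytest.approx(-4.60, abs=0.05)
    L9 = linearize(9.0, params)
    assert L9.lambda_re == pytest.approx(-0.015, abs=0.005)
    assert L9.omega == pytest.approx(0.578, abs=0.005)


def test_complex_pair_dominates_subthreshold(params):
    # one complex pair with |Re| << omega across the bistable range
    for I in np.arange(5.0, 9.01, 0.5):
        L = linearize(I, params)
        assert abs(L.lambda_re) / L.omega < 0.25
        assert L.ev_slow < 0 and L.ev_fast < L.ev_slow


def test_hopf_location_and_bracketing(params):
    I1 = find_hopf(params)
    assert I1 == pytest.approx(9.8, abs=0.1)
    assert linearize(I1 - 0.5, params).lambda_re < 0
    assert linearize(I1 + 0.5, params).lambda_re > 0


def test_hopf_requires_sign_change(params):
    with pytest.raises(RuntimeError):
        find_hopf(params, bracket=(0.0, 4.0))


def test_bistability_endpoints(params):
    # at I = 10 spiking persists; at I = 5 the trajectory settles to rest
    y0 = spiking_initial_state(params)
    assert sustained_spiking(10.0, params, y0, transient=200.0, observe=1200.0)
    assert not sustained_spiking(5.0, params, y0, transient=200.0, observe=1200.0)


def test_integration_step_halving_stable(params):
    # the spiking classification is step-size independent
    y0 = spiking_initial_state(params)
    for dt in (0.02, 0.01):
        assert sustained_spiking(8.0, params, y0, transient=200.0, observe=1200.0, dt=dt)


def test_integrate_preserves_fixed_point(params):
    fp = find_fixed_point(6.0, params)
    t, Y = integrate(6.0, 50.0, params, y0=fp, dt=0.01)
    assert np.max(np.abs(Y[:, 0] - fp.V)) < 1e-6
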