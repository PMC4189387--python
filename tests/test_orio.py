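"""The 13-SDE Langevin model: drift structure, noise structure, protocol."""

import numpy as np
import pytest

from stochhh import HHParameters, SimConfig, find_fixed_point, gate_rates, simulate_orio
from stochhh.common import stationary_state_distribution
from stochhh.orio import OrioState, equilibrium_state, orio_drift, orio_noise_increments, orio_step


def random_state(rng) -> tuple[np.ndarray, np.ndarray, float]:
    k = rng.dirichlet(np.ones(5))
    s = rng.dirichlet(np.ones(8))
    V = rng.uniform(-90, 30)
    return k, s, V


@pytest.mark.parametrize("seed", range(5))
def test_drift_components_sum_to_zero(seed):
    rng = np.random.default_rng(seed)
    k, s, V = random_state(rng)
    dk, ds = orio_drift(k, s, gate_rates(V))
    assert np.sum(dk) == pytest.approx(0.0, abs=1e-14)
    assert np.sum(ds) == pytest.approx(0.0, abs=1e-14)


def test_drift_vanishes_at_stationary_law():
    # detailed balance of the single-channel chain at clamped voltage
    for V in (-70.0, -60.0, -40.0):
        pk, pna = stationary_state_distribution(V)
        dk, ds = orio_drift(pk, pna, gate_rates(V))
        assert np.max(np.abs(dk)) < 1e-12
        assert np.max(np.abs(ds)) < 1e-12


def test_drift_with_all_mass_in_first_state():
    V = -60.0
    r = gate_rates(V)
    k = np.array([1.0, 0, 0, 0, 0])
    s = np.zeros(8)
    s[0] = 1.0
    dk, _ = orio_drift(k, s, r)
    assert dk[0] == pytest.approx(-4 * r.alpha_n)
    assert dk[1] == pytest.approx(4 * r.alpha_n)
    assert np.all(dk[2:] == 0)


@pytest.mark.parametrize("seed", range(3))
def test_noise_increments_cancel_chainwise(seed, params):
    rng = np.random.default_rng(seed)
    k, s, V = random_state(rng)
    nk, ns = orio_noise_increments(k, s, gate_rates(V), params, 0.005, rng)
    assert np.sum(nk) == pytest.approx(0.0, abs=1e-15)
    assert np.sum(ns) == pytest.approx(0.0, abs=1e-15)


def test_noise_scales_inversely_with_sqrt_channel_count(params, rng):
    # quadrupling the area (4x NK) halves every increment, draw for draw
    k, s, V = random_state(rng)
    zK, zNa = rng.standard_normal(4), rng.standard_normal(10)
    r = gate_rates(V)
    nk1, ns1 = orio_noise_increments(k, s, r, params, 0.005, rng, zK=zK, zNa=zNa)
    big = params.with_area(4 * params.area)
    nk4, ns4 = orio_noise_increments(k, s, r, big, 0.005, rng, zK=zK, zNa=zNa)
    assert np.allclose(nk4, nk1 / 2)
    assert np.allclose(ns4, ns1 / 2)


def test_open_state_increment_variance_matches_flux_sum(params):
    # Var(dn4) = dt * (alpha_n n3 + 4 beta_n n4) / NK
    rng = np.random.default_rng(7)
    V, dt = -60.0, 0.005
    r = gate_rates(V)
    pk, pna = stationary_state_distribution(V)
    draws = np.array([
        orio_noise_increments(pk, pna, r, params, dt, rng)[0][4] for _ in range(100_000)
    ])
    expected = dt * (r.alpha_n * pk[3] + 4 * r.beta_n * pk[4]) / params.NK
    assert draws.var() == pytest.approx(expected, rel=0.03)
    assert draws.mean() == pytest.approx(0.0, abs=4 * np.sqrt(expected / len(draws)))


def test_step_renormalizes_both_chains(params, rng):
    st = equilibrium_state(6.0, params)
    for _ in range(50):
        st = orio_step(st, 6.0, params, 0.005, rng)
        assert st.k.sum() == pytest.approx(1.0, abs=1e-12)
        assert st.s.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(st.k >= 0) and np.all(st.s >= 0)


def test_zero_noise_run_stays_at_fixed_point(params):
    # the noiseless 13-ODE system from stationary fractions at the I=0
    # fixed point is an equilibrium of the master-equation dynamics
    fp = find_fixed_point(0.0, params)
    cfg = SimConfig(I=0.0, params=params, seed=0, duration=100.0,
                    noise_scale=0.0, record_trace=True, trace_stride=20)
    res = simulate_orio(cfg)
    t, v = res.trace
    assert np.max(np.abs(v - fp.V)) < 0.01


def test_simulation_reproducible_and_isis_positive(params):
    cfg = SimConfig(I=6.5, params=HHParameters(area=200.0), seed=42, target_isis=60, ensemble=2)
    r1 = simulate_orio(cfg)
    r2 = simulate_orio(cfg)
    assert np.array_equal(r1.isis, r2.isis)
    assert len(r1.isis) >= 60
    assert np.all(r1.isis > 0)
    for st in r1.spike_trains:
        assert np.all(np.diff(st) > 0)


def test_config_rejects_ambiguous_stop_rule(params):
    with pytest.raises(ValueError):
        SimConfig(I=6.0, params=params, duration=100.0, target_isis=10)
    with pytest.raises(ValueError):
        SimConfig(I=6.0, params=params)
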