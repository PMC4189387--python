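"""Exact channel-state Markov chain: propensities, stationarity, limits."""

import numpy as np
import pytest
from scipy import stats

from stochhh import (
    ChannelCounts,
    HHParameters,
    SimConfig,
    gate_rates,
    sample_initial_counts,
    simulate_micro,
    simulate_micro_clamped,
    transition_rates,
)
from stochhh.common import stationary_state_distribution


def test_single_occupied_state_propensities(params):
    counts = ChannelCounts(k=[params.NK, 0, 0, 0, 0], s=[params.NNa, 0, 0, 0, 0, 0, 0, 0])
    V = -60.0
    r = gate_rates(V)
    props = dict(transition_rates(counts, V, params))
    nonzero_k = {e: p for e, p in props.items() if e[0] == "K" and p > 0}
    assert nonzero_k == {("K", 0, 1): pytest.approx(params.NK * 4 * r.alpha_n)}


def test_propensities_linear_in_channel_number(params):
    rng = np.random.default_rng(0)
    k = rng.multinomial(100, np.ones(5) / 5)
    s = rng.multinomial(300, np.ones(8) / 8)
    p1 = np.array([p for _, p in transition_rates(ChannelCounts(k=k, s=s), -55.0)])
    p2 = np.array([p for _, p in transition_rates(ChannelCounts(k=2 * k, s=2 * s), -55.0)])
    assert np.allclose(p2, 2 * p1)


def test_closed_to_open_edge_rate_at_minus65():
    counts = ChannelCounts(k=[0, 0, 0, 0, 1], s=[1, 0, 0, 0, 0, 0, 0, 0])
    props = dict(transition_rates(counts, -65.0))
    # beta_n(-65) = 0.125, multiplicity 4
    assert props[("K", 4, 3)] == pytest.approx(0.5)


def test_initial_counts_conserve_totals_and_match_binomial_mean(params):
    rng = np.random.default_rng(5)
    V = -63.0
    r = gate_rates(V)
    p_open = r.alpha_n / (r.alpha_n + r.beta_n)
    fracs = []
    for _ in range(300):
        c = sample_initial_counts(V, params, rng)
        assert c.k.sum() == params.NK
        assert c.s.sum() == params.NNa
        fracs.append(c.k[4] / params.NK)
    expected = p_open**4
    se = np.sqrt(expected * (1 - expected) / (params.NK * 300))
    assert np.mean(fracs) == pytest.approx(expected, abs=4 * se)


def test_initial_counts_follow_product_binomial_law(small_params):
    # chi-square on pooled state counts over many independent draws
    rng = np.random.default_rng(17)
    pk, pna = stationary_state_distribution(-65.0)
    tot_k = np.zeros(5)
    tot_na = np.zeros(8)
    n_draws = 2000
    for _ in range(n_draws):
        c = sample_initial_counts(-65.0, small_params, rng)
        tot_k += c.k
        tot_na += c.s
    chi_k = stats.chisquare(tot_k, pk * n_draws * small_params.NK)
    assert chi_k.pvalue > 0.01
    # pool the rarest sodium states to keep expected counts reasonable
    exp_na = pna * n_draws * small_params.NNa
    keep = exp_na >= 5
    if keep.all():
        obs, exp = tot_na, exp_na
    else:
        obs = np.append(tot_na[keep], tot_na[~keep].sum())
        exp = np.append(exp_na[keep], exp_na[~keep].sum())
    assert stats.chisquare(obs, exp).pvalue > 0.01


def test_clamped_occupancy_matches_stationary_law(small_params):
    # time-averaged open-state occupancy under voltage clamp
    fk, fna = simulate_micro_clamped(-65.0, small_params, duration=5000.0, seed=3)
    pk, pna = stationary_state_distribution(-65.0)
    # batch-mean standard error via independent replicate runs
    reps = [simulate_micro_clamped(-65.0, small_params, 1000.0, seed=100 + i)[0][4] for i in range(5)]
    se = np.std(reps, ddof=1) / np.sqrt(5)
    assert fk[4] == pytest.approx(pk[4], abs=max(3 * se, 0.003))
    assert np.allclose(fk, pk, atol=0.02)
    assert np.allclose(fna, pna, atol=0.02)


def test_free_run_spikes_and_conserves_channels(params):
    small = HHParameters(area=50.0)
    res = simulate_micro(SimConfig(I=6.5, params=small, seed=9, duration=1500.0))
    # conservation is checked at every event inside the kernel and would raise
    spikes = res.spike_trains[0]
    assert len(spikes) >= 3
    assert np.all(np.diff(spikes) > 0)
    assert np.all(res.isis > 0)


def test_reproducible_given_seed(params):
    small = HHParameters(area=30.0)
    cfg = SimConfig(I=7.0, params=small, seed=21, duration=800.0)
    r1 = simulate_micro(cfg)
    r2 = simulate_micro(cfg)
    assert np.array_equal(np.concatenate(r1.spike_trains), np.concatenate(r2.spike_trains))


def test_large_area_limit_approaches_deterministic_period(params):
    # as the channel count grows the stochastic firing period converges to
    # the deterministic limit-cycle period (diffusion-limit consistency)
    from stochhh import detect_spikes, integrate
    from stochhh.deterministic import spiking_initial_state

    y0 = spiking_initial_state(params)
    t, Y = integrate(10.0, 200.0, params, y0=y0, dt=0.005)
    per_det = np.diff(detect_spikes(t, Y[:, 0]))[-5:].mean()

    big = HHParameters(area=2000.0)
    res = simulate_micro(SimConfig(I=10.0, params=big, seed=4, duration=150.0))
    isis = res.isis
    assert len(isis) >= 4
    mc_se = isis.std(ddof=1) / np.sqrt(len(isis))
    assert abs(isis.mean() - per_det) < 0.02 * per_det + 3 * mc_se
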