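"""ISI analysis: spike detection, histograms, three-part decomposition."""

import numpy as np
import pytest

from stochhh import (
    ISIMixtureSpec,
    detect_bumps,
    detect_spikes,
    compute_isis,
    extract_features,
    fit_tail_exponent,
    generate_modulated_exponential,
    generate_synthetic_isis,
    make_histogram,
    run_probability,
)
from stochhh.isi import ISIHistogram, SpikeTrain


# ---------------------------------------------------------------- spikes

def test_constant_trace_has_no_spikes():
    t = np.arange(100.0)
    assert len(detect_spikes(t, np.full(100, -65.0), 0.0)) == 0


def test_triangular_pulses_give_interpolated_downcrossings():
    # two triangles peaking at 40 mV; downward crossing of 0 is midway
    t = np.arange(0.0, 20.0, 1.0)
    v = np.full_like(t, -65.0)
    for peak in (5, 13):
        v[peak - 1], v[peak], v[peak + 1] = -10.0, 40.0, -10.0
    sp = detect_spikes(t, v, 0.0)
    assert len(sp) == 2
    assert sp[0] == pytest.approx(5 + 40.0 / 50.0)
    assert sp[1] == pytest.approx(13 + 40.0 / 50.0)


def test_spike_times_invariant_to_common_offset():
    rng = np.random.default_rng(0)
    t = np.arange(0.0, 50.0, 0.1)
    v = -60 + 50 * np.sin(t) + rng.normal(0, 1, len(t))
    assert np.allclose(detect_spikes(t, v, -20.0), detect_spikes(t, v + 17.3, -2.7))


def test_nonmonotone_grid_rejected():
    with pytest.raises(ValueError):
        detect_spikes([0.0, 2.0, 1.0], [0.0, 1.0, -1.0])


def test_compute_isis():
    assert np.allclose(compute_isis([10.0, 25.0, 60.0]), [15.0, 35.0])
    assert len(compute_isis([5.0])) == 0
    isis = compute_isis(SpikeTrain(times=np.sort(np.random.default_rng(1).uniform(0, 1e4, 200))))
    assert len(isis) == 199 and np.all(isis > 0)


# ------------------------------------------------------------- histogram

def test_histogram_masses_sum_to_one():
    rng = np.random.default_rng(2)
    isis = rng.exponential(20.0, 5000)
    for bw in (0.5, 1.0, 2.0):
        h = make_histogram(isis, bw)
        assert h.masses.sum() == pytest.approx(1.0)
        assert np.all(h.masses >= 0)


def test_histogram_single_value():
    h = make_histogram(np.full(10, 7.3), 1.0)
    assert h.masses.max() == pytest.approx(1.0)
    assert np.count_nonzero(h.masses) == 1


def test_histogram_rejects_empty():
    with pytest.raises(ValueError):
        make_histogram(np.empty(0))


# ------------------------------------------------------------- tail fit

def test_tail_mle_recovers_known_rate():
    rng = np.random.default_rng(3)
    t0, rate = 30.0, 0.05
    isis = t0 + rng.exponential(1 / rate, 100_000)
    est, se = fit_tail_exponent(isis, t0)
    assert abs(est - rate) < 3 * se
    assert se == pytest.approx(rate / np.sqrt(100_000), rel=0.05)


def test_tail_fit_shift_invariant():
    rng = np.random.default_rng(4)
    isis = 10.0 + rng.exponential(25.0, 5000)
    r1, _ = fit_tail_exponent(isis, 12.0)
    r2, _ = fit_tail_exponent(isis + 100.0, 112.0)
    assert r1 == pytest.approx(r2)


def test_tail_fit_needs_enough_points():
    with pytest.raises(ValueError, match="need >="):
        fit_tail_exponent(np.arange(1.0, 30.0), t0=25.0)


# -------------------------------------------------------- run probability

def test_run_probability_saturates():
    assert run_probability([1.0, 2.0, 3.0], 10.0) == 1.0


def test_run_probability_on_known_mixture():
    rng = np.random.default_rng(5)
    n = 50_000
    short = rng.normal(12.0, 1.0, int(0.7 * n))
    long = 80.0 + rng.exponential(30.0, n - len(short))
    p = run_probability(np.concatenate([short, long]), 30.0)
    assert p == pytest.approx(0.70, abs=3 * np.sqrt(0.7 * 0.3 / n))


# ----------------------------------------------------------------- bumps

def test_pure_exponential_has_no_bumps():
    # exact exponential masses: strictly decreasing, no local maxima
    edges = np.arange(0.0, 200.0, 1.0)
    masses = np.exp(-0.04 * edges[:-1])
    masses /= masses.sum()
    hist = ISIHistogram(edges=edges, masses=masses, n_total=100_000)
    locs, spacing = detect_bumps(hist)
    assert len(locs) == 0 and spacing is None


def test_bump_spacing_recovered_from_modulated_density():
    period = 12.0
    sample = generate_modulated_exponential(rate=0.04, period=period, amplitude=0.5,
                                            n=100_000, seed=6)
    hist = make_histogram(sample, 1.0)
    locs, spacing = detect_bumps(hist)
    assert len(locs) >= 2
    assert spacing == pytest.approx(period, abs=1.0)


# ---------------------------------------------------------- full pipeline

def test_features_recovered_from_three_part_mixture():
    spec = ISIMixtureSpec()
    n = 100_000
    isis, labels = generate_synthetic_isis(spec, n, seed=7)
    f = extract_features(isis)
    assert abs(f.tail_exponent - spec.tail_rate) < 3 * np.sqrt(
        f.tail_se**2 + (spec.tail_rate / np.sqrt(f.n_tail)) ** 2
    )
    se_run = np.sqrt(spec.peak_mass * (1 - spec.peak_mass) / n)
    assert f.run_probability == pytest.approx(spec.peak_mass, abs=4 * se_run)
    assert f.peak_location == pytest.approx(spec.peak_loc, abs=1.0)
    if f.bump_spacing is not None:
        assert f.bump_spacing == pytest.approx(spec.bump_period, abs=1.5)


def test_features_permutation_invariant():
    isis, _ = generate_synthetic_isis(ISIMixtureSpec(), 20_000, seed=8)
    f1 = extract_features(isis)
    f2 = extract_features(np.random.default_rng(0).permutation(isis))
    assert f1.tail_exponent == f2.tail_exponent
    assert f1.run_probability == f2.run_probability
    assert f1.t_cut == f2.t_cut and f1.t0 == f2.t0


def test_run_probability_closure():
    # mass below t_cut and mass at-or-above t_cut partition the sample
    isis, _ = generate_synthetic_isis(ISIMixtureSpec(), 10_000, seed=9)
    f = extract_features(isis)
    assert f.run_probability + np.mean(isis >= f.t_cut) == pytest.approx(1.0)


def test_tail_interval_calibration():
    # +-3 SE covers the true rate in >= 99% of repeated synthetic samples
    rng = np.random.default_rng(10)
    rate, n, hits = 0.04, 2000, 0
    trials = 200
    for _ in range(trials):
        sample = rng.exponential(1 / rate, n)
        est, se = fit_tail_exponent(sample, 0.0, min_tail=50)
        hits += abs(est - rate) <= 3 * se
    assert hits / trials >= 0.99


# ------------------------------------------------------ synthetic sampler

def test_mixture_component_fractions():
    spec = ISIMixtureSpec(peak_mass=0.5, bump_mass=0.2, tail_mass=0.3)
    isis, labels = generate_synthetic_isis(spec, 100_000, seed=11)
    fracs = np.bincount(labels, minlength=3) / len(labels)
    for frac, m in zip(fracs, (0.5, 0.2, 0.3)):
        assert frac == pytest.approx(m, abs=3 * np.sqrt(m * (1 - m) / 100_000))
    assert np.all(isis > 0)


def test_mixture_spec_validates_masses():
    with pytest.raises(ValueError):
        ISIMixtureSpec(peak_mass=0.5, bump_mass=0.2, tail_mass=0.4)


def test_peak_only_spec():
    spec = ISIMixtureSpec(peak_mass=1.0, bump_mass=0.0, tail_mass=0.0)
    isis, labels = generate_synthetic_isis(spec, 1000, seed=12)
    assert np.all(labels == 0)
    assert isis.mean() == pytest.approx(spec.peak_loc, abs=0.2)
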