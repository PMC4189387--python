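"""Exact channel-state Markov chain ("Micro") simulated by Gillespie sampling.

Every potassium channel occupies one of 5 states (number of open n-gates)
and every sodium channel one of 8 states (open m-gates x h-gate); a
transition moves exactly one channel along one edge of the state network,
with propensity = (channels in the source state) x (per-channel rate with
the network's gate multiplicity).  Event times are exponential in the
total propensity; between events the voltage is integrated with channel
counts frozen, with a propensity-drift guard that redraws the event if
the rates become stale.  This is the gold-standard stochastic model the
Langevin approximations are judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .common import (
    SimConfig,
    SimResult,
    child_seed,
    pool_isis,
    register_simulator,
    stationary_state_distribution,
)
from .deterministic import find_fixed_point
from .params import HHParameters
from .rates import gate_rates

__all__ = [
    "ChannelCounts",
    "transition_rates",
    "sample_initial_counts",
    "simulate_micro",
    "simulate_micro_clamped",
]


@dataclass
class ChannelCounts:
    """Integer channel occupancies: 5 potassium states, 8 sodium states."""

    k: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.s = np.asarray(self.s, dtype=np.int64)
        if self.k.shape != (5,) or self.s.shape != (8,):
            raise ValueError("expected 5 potassium and 8 sodium state counts")
        if np.any(self.k < 0) or np.any(self.s < 0):
            raise ValueError("channel counts must be non-negative")


def transition_rates(
    counts: ChannelCounts, V: float, params: HHParameters | None = None
) -> list[tuple[tuple[str, int, int], float]]:
    """All 28 directed-edge propensities (1/ms) at voltage ``V``.

    Returns ``((chain, src, dst), propensity)`` tuples: 8 directed
    potassium edges and 20 directed sodium edges.
    """
    r = gate_rates(V)
    out: list[tuple[tuple[str, int, int], float]] = []
    for j in range(4):
        out.append((("K", j, j + 1), (4 - j) * r.alpha_n * counts.k[j]))
        out.append((("K", j + 1, j), (j + 1) * r.beta_n * counts.k[j + 1]))
    for a, b, fm, bm in zip(
        _kernels.NA_EDGE_A, _kernels.NA_EDGE_B, _kernels.NA_FWD_MULT, _kernels.NA_BWD_MULT
    ):
        if fm > 0:
            fwd, bwd = fm * r.alpha_m, bm * r.beta_m
        else:
            fwd, bwd = r.alpha_h, r.beta_h
        out.append((("Na", int(a), int(b)), fwd * counts.s[a]))
        out.append((("Na", int(b), int(a)), bwd * counts.s[b]))
    return out


def sample_initial_counts(
    V: float, params: HHParameters, rng: np.random.Generator
) -> ChannelCounts:
    """Draw channel counts from the stationary law at clamped ``V``.

    Channels are independent and identically distributed, so the state
    counts are exactly multinomial over the product-binomial
    single-channel law; totals equal NK and NNa by construction.
    """
    pk, pna = stationary_state_distribution(V)
    return ChannelCounts(
        k=rng.multinomial(params.NK, pk),
        s=rng.multinomial(params.NNa, pna),
    )


def _run_micro_trajectory(
    seed: int,
    config: SimConfig,
    init: ChannelCounts,
    V0: float,
    t_max: float,
    max_spikes: int,
    guard: float,
    event_budget: int,
):
    params = config.params
    capacity = max_spikes if max_spikes > 0 else max(int(t_max / 4.0) + 16, 64)
    spike_out = np.empty(capacity)
    occ_k = np.zeros(5)
    occ_na = np.zeros(8)
    status, n_spk, t_end, n_events, violations = _kernels.micro_core(
        seed, config.I, config.dt,
        params.gK_max, params.gNa_max, params.gL,
        params.VK, params.VNa, params.VL, params.C,
        params.NK, params.NNa,
        V0, init.k, init.s,
        config.threshold, t_max, max_spikes,
        False, guard, event_budget,
        spike_out, occ_k, occ_na,
    )
    if violations:
        raise AssertionError(
            f"channel-total conservation violated {violations} times (internal error)"
        )
    if status == _kernels.BUDGET_EXCEEDED:
        raise RuntimeError(
            f"event budget {event_budget} exhausted at t={t_end:.1f} ms "
            f"({n_spk} spikes); raise event_budget or reduce area/duration"
        )
    return spike_out[: min(n_spk, capacity)].copy(), t_end


def simulate_micro(
    config: SimConfig, guard: float = 0.05, event_budget: int = 2_000_000_000
) -> SimResult:
    """Simulate the exact Markov chain, pooling ISIs over an ensemble.

    Initial condition: stationary channel counts at the deterministic
    fixed-point voltage for the run's current; the first spike of each
    trajectory is discarded.  ``guard`` is the relative propensity drift
    tolerated during an event's waiting time before it is redrawn.
    """
    params = config.params
    fp = find_fixed_point(config.I, params)
    if config.duration is not None:
        max_spikes = 0
        t_max = config.duration
    else:
        max_spikes = config.spikes_per_trajectory()
        t_max = config.ms_per_spike_budget * max_spikes
    spike_trains: list[np.ndarray] = []
    t_total = 0.0
    for traj in range(config.ensemble):
        seed = child_seed(config.seed, "micro", traj)
        init = sample_initial_counts(
            fp.V, params, np.random.default_rng(child_seed(config.seed, "micro-init", traj))
        )
        spikes, t_end = _run_micro_trajectory(
            seed, config, init, fp.V, t_max, max_spikes, guard, event_budget
        )
        spike_trains.append(spikes)
        t_total += t_end
    isis = pool_isis(spike_trains)
    if config.target_isis is not None:
        isis = isis[: config.target_isis] if len(isis) > config.target_isis else isis
    return SimResult(
        model="micro",
        spike_trains=spike_trains,
        isis=isis,
        t_total=t_total,
        manifest=config.manifest("micro") | {"guard": guard},
        trace=None,
    )


def simulate_micro_clamped(
    V: float,
    params: HHParameters,
    duration: float,
    seed: int = 0,
    event_budget: int = 2_000_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-clamped Gillespie run; returns time-averaged state fractions.

    With the voltage held fixed the chain is a time-homogeneous Markov
    chain whose stationary law is the product-binomial single-channel
    distribution; the returned occupancies are time-weighted averages
    over the run, normalized to fractions.
    """
    rng = np.random.default_rng(child_seed(seed, "micro-clamp-init"))
    init = sample_initial_counts(V, params, rng)
    spike_out = np.empty(1)
    occ_k = np.zeros(5)
    occ_na = np.zeros(8)
    status, _n_spk, t_end, n_events, violations = _kernels.micro_core(
        child_seed(seed, "micro-clamp"), 0.0, 0.005,
        params.gK_max, params.gNa_max, params.gL,
        params.VK, params.VNa, params.VL, params.C,
        params.NK, params.NNa,
        V, init.k, init.s,
        0.0, duration, 0,
        True, 0.05, event_budget,
        spike_out, occ_k, occ_na,
    )
    if violations:
        raise AssertionError("channel-total conservation violated (internal error)")
    if status == _kernels.BUDGET_EXCEEDED:
        raise RuntimeError(f"event budget exhausted at t={t_end:.1f} ms")
    return occ_k / (t_end * params.NK), occ_na / (t_end * params.NNa)


register_simulator("micro", simulate_micro)
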