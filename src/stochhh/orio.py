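"""The 13-SDE Langevin approximation with shared per-edge noise.

Each of the 5 potassium and 8 sodium channel-state fractions gets its own
stochastic differential equation.  The drift of a state is the net
deterministic flow over its transition edges; each *edge* carries one
Gaussian noise term whose standard deviation is sqrt of the summed
directed fluxes over the edge divided by the channel count, entering the
two incident state equations with opposite signs.  This is the diffusion
approximation of the channel-state Markov chain for density-dependent
populations (error of order log(N)/N), written without any matrix square
root: 4 noise draws for the potassium chain, 10 for the sodium chain.

Integration is Euler-Maruyama with the boundary protocol: a negative
potassium fraction triggers a redraw of that chain's noises, a negative
sodium fraction is reset to zero, both chains are renormalized to sum 1
after every step, and only then is the voltage advanced.
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
from .rates import RateSet, gate_rates

__all__ = [
    "OrioState",
    "K_EDGES",
    "NA_EDGES",
    "orio_drift",
    "orio_noise_increments",
    "orio_step",
    "simulate_orio",
    "equilibrium_state",
]

# (src, dst, per-channel forward rate multiplier, backward multiplier,
#  gate kind) for every undirected edge; kind "m"/"h" selects the rate
# pair for sodium, potassium edges all use (alpha_n, beta_n).
K_EDGES = [(j, j + 1, 4 - j, j + 1) for j in range(4)]
NA_EDGES = [
    (int(a), int(b), int(fm), int(bm), "m" if fm > 0 else "h")
    for a, b, fm, bm in zip(
        _kernels.NA_EDGE_A, _kernels.NA_EDGE_B, _kernels.NA_FWD_MULT, _kernels.NA_BWD_MULT
    )
]


@dataclass
class OrioState:
    """Voltage plus channel-state fractions (5 potassium, 8 sodium)."""

    V: float
    k: np.ndarray
    s: np.ndarray

    def copy(self) -> "OrioState":
        return OrioState(self.V, self.k.copy(), self.s.copy())


def equilibrium_state(I: float, params: HHParameters) -> OrioState:
    """Deterministic fixed-point voltage with stationary channel fractions."""
    fp = find_fixed_point(I, params)
    pk, pna = stationary_state_distribution(fp.V)
    return OrioState(V=fp.V, k=pk, s=pna)


def _edge_fluxes(k: np.ndarray, s: np.ndarray, rates: RateSet):
    """Directed fluxes (forward, backward) per edge for both chains."""
    kf = np.array([(4 - j) * rates.alpha_n * k[j] for j in range(4)])
    kb = np.array([(j + 1) * rates.beta_n * k[j + 1] for j in range(4)])
    nf = np.empty(10)
    nb = np.empty(10)
    for e, (a, b, fm, bm, kind) in enumerate(NA_EDGES):
        if kind == "m":
            nf[e] = fm * rates.alpha_m * s[a]
            nb[e] = bm * rates.beta_m * s[b]
        else:
            nf[e] = rates.alpha_h * s[a]
            nb[e] = rates.beta_h * s[b]
    return kf, kb, nf, nb


def orio_drift(k: np.ndarray, s: np.ndarray, rates: RateSet) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drift of the 13 state fractions (1/ms).

    Every edge contributes its net flux with opposite signs to its two
    incident states, so each chain's drift components sum to zero.
    """
    kf, kb, nf, nb = _edge_fluxes(k, s, rates)
    dk = np.zeros(5)
    for j, (a, b, _, _) in enumerate(K_EDGES):
        net = kf[j] - kb[j]
        dk[a] -= net
        dk[b] += net
    ds = np.zeros(8)
    for e, (a, b, *_rest) in enumerate(NA_EDGES):
        net = nf[e] - nb[e]
        ds[a] -= net
        ds[b] += net
    return dk, ds


def orio_noise_increments(
    k: np.ndarray,
    s: np.ndarray,
    rates: RateSet,
    params: HHParameters,
    dt: float,
    rng: np.random.Generator,
    zK: np.ndarray | None = None,
    zNa: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic increments for one Euler-Maruyama step.

    One standard normal per edge (4 potassium, 10 sodium), scaled by
    sqrt((flux_fwd + flux_bwd) / N) * sqrt(dt) and applied with opposite
    signs to the incident states.  ``zK`` / ``zNa`` may be supplied to
    fix the draws (used by tests and the redraw protocol).
    """
    kf, kb, nf, nb = _edge_fluxes(k, s, rates)
    if np.any(kf + kb < 0) or np.any(nf + nb < 0):
        raise ValueError("negative flux sum: state fractions must be non-negative")
    zK = rng.standard_normal(4) if zK is None else zK
    zNa = rng.standard_normal(10) if zNa is None else zNa
    sq = np.sqrt(dt)
    nk = np.zeros(5)
    for j, (a, b, _, _) in enumerate(K_EDGES):
        amp = np.sqrt((kf[j] + kb[j]) / params.NK) * sq * zK[j]
        nk[a] -= amp
        nk[b] += amp
    ns = np.zeros(8)
    for e, (a, b, *_rest) in enumerate(NA_EDGES):
        amp = np.sqrt((nf[e] + nb[e]) / params.NNa) * sq * zNa[e]
        ns[a] -= amp
        ns[b] += amp
    return nk, ns


def orio_step(
    state: OrioState,
    I: float,
    params: HHParameters,
    dt: float,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
    redraw_budget: int = 100,
) -> OrioState:
    """One Euler-Maruyama step (reference NumPy implementation).

    Order of operations: channel update, boundary rules, normalization,
    then the voltage update from the fresh conducting fractions.
    """
    rates = gate_rates(state.V)
    dk, ds = orio_drift(state.k, state.s, rates)
    nk, ns = orio_noise_increments(state.k, state.s, rates, params, dt, rng)
    new_k = state.k + dt * dk + noise_scale * nk
    for _ in range(redraw_budget):
        if np.all(new_k >= 0):
            break
        nk, _unused = orio_noise_increments(
            state.k, state.s, rates, params, dt, rng, zNa=np.zeros(10)
        )
        new_k = state.k + dt * dk + noise_scale * nk
    else:
        raise RuntimeError(
            f"potassium redraw budget ({redraw_budget}) exhausted; reduce dt"
        )
    new_s = state.s + dt * ds + noise_scale * ns
    new_s[new_s < 0] = 0.0
    new_k /= new_k.sum()
    new_s /= new_s.sum()
    V = state.V + dt * (
        I
        - params.gNa_max * new_s[7] * (state.V - params.VNa)
        - params.gK_max * new_k[4] * (state.V - params.VK)
        - params.gL * (state.V - params.VL)
    ) / params.C
    return OrioState(V=float(V), k=new_k, s=new_s)


def simulate_orio(config: SimConfig) -> SimResult:
    """Simulate the 13-SDE model, pooling ISIs over an ensemble.

    Every trajectory starts at the deterministic fixed point with
    stationary channel fractions and gets an independently derived child
    seed; the first spike of each trajectory is discarded.
    """
    params = config.params
    init = equilibrium_state(config.I, params)
    spike_trains: list[np.ndarray] = []
    t_total = 0.0
    trace = None
    if config.duration is not None:
        max_spikes = 0
        t_max = config.duration
        capacity = max(int(t_max / 4.0) + 16, 64)
    else:
        max_spikes = config.spikes_per_trajectory()
        t_max = config.ms_per_spike_budget * max_spikes
        capacity = max_spikes
    n_steps_max = int(round(t_max / config.dt))
    for traj in range(config.ensemble):
        seed = child_seed(config.seed, "orio", traj)
        spike_out = np.empty(capacity)
        if config.record_trace and traj == 0:
            n_rec = n_steps_max // config.trace_stride + 1
            rec_v = np.empty(n_rec)
            stride = config.trace_stride
        else:
            rec_v = np.empty(1)
            stride = 0
        status, n_spk, t_end, n_rec = _kernels.orio_core(
            seed, config.I, config.dt,
            params.gK_max, params.gNa_max, params.gL,
            params.VK, params.VNa, params.VL, params.C,
            params.NK, params.NNa,
            init.V, init.k, init.s,
            config.threshold, n_steps_max, max_spikes,
            config.noise_scale, config.redraw_budget,
            spike_out, stride, rec_v,
        )
        if status == _kernels.REDRAW_EXHAUSTED:
            raise RuntimeError(
                f"potassium redraw budget exhausted at t={t_end:.3f} ms; reduce dt"
            )
        if status == _kernels.BUDGET_EXCEEDED:
            raise RuntimeError(
                f"stop rule not reached within {t_max:.0f} ms "
                f"({n_spk} spikes); raise ms_per_spike_budget"
            )
        spike_trains.append(spike_out[: min(n_spk, capacity)].copy())
        t_total += t_end
        if stride > 0:
            trace = (np.arange(n_rec) * config.dt * stride, rec_v[:n_rec].copy())
    isis = pool_isis(spike_trains)
    if config.target_isis is not None:
        isis = isis[: config.target_isis] if len(isis) > config.target_isis else isis
    return SimResult(
        model="orio",
        spike_trains=spike_trains,
        isis=isis,
        t_total=t_total,
        manifest=config.manifest("orio"),
        trace=trace,
    )


register_simulator("orio", simulate_orio)
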