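"""The 7-SDE Langevin model with harmonic-oscillator colored noise.

Instead of one SDE per channel state, this model keeps the three classic
gating variables (n, m, h) with fluctuation-dissipation noise, and adds
two stochastic harmonic ("Brownian") oscillator pairs (qK, pK) and
(qNa, pNa) that modulate the conducting fractions:

    psiK  = n^4   + sqrt(n^4 (1 - n^4) / NK) * qK
    psiNa = m^3 h + sqrt(m^3 (1 - m^3) / NNa) * h * qNa

The oscillators model the persistence of cross-correlations between
voltage fluctuations and open-channel fluctuations that arise from gate
multiplicity.  Their stiffness tracks the gate relaxation rate
(alpha + beta), with fixed phenomenological constants

    gammaK = gammaNa = 10, omegaK^2 = 150, omegaNa^2 = 200,
    TK = 400, TNa = 800.

Only 5 Gaussian draws are needed per step, which makes this the fastest
of the Langevin models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .common import SimConfig, SimResult, child_seed, pool_isis, register_simulator
from .deterministic import find_fixed_point
from .params import HHParameters
from .rates import gate_rates

__all__ = [
    "GAMMA_K", "GAMMA_NA", "OMEGA2_K", "OMEGA2_NA", "T_K", "T_NA",
    "GulerState", "psi_K", "psi_Na", "guler_step", "simulate_guler",
]

GAMMA_K = 10.0
GAMMA_NA = 10.0
OMEGA2_K = 150.0
OMEGA2_NA = 200.0
T_K = 400.0
T_NA = 800.0


@dataclass(frozen=True)
class GulerState:
    """(V, n, m, h) plus the two oscillator pairs, all dimensionless
    except V (mV).  Oscillators start at rest (0)."""

    V: float
    n: float
    m: float
    h: float
    qK: float = 0.0
    pK: float = 0.0
    qNa: float = 0.0
    pNa: float = 0.0


def psi_K(state: GulerState, NK: int) -> float:
    """Effective open fraction of potassium channels."""
    n4 = state.n**4
    return n4 + np.sqrt(max(n4 * (1.0 - n4), 0.0) / NK) * state.qK


def psi_Na(state: GulerState, NNa: int) -> float:
    """Effective open fraction of sodium channels."""
    m3 = state.m**3
    return m3 * state.h + np.sqrt(max(m3 * (1.0 - m3), 0.0) / NNa) * state.h * state.qNa


def equilibrium_state(I: float, params: HHParameters) -> GulerState:
    fp = find_fixed_point(I, params)
    return GulerState(V=fp.V, n=fp.n, m=fp.m, h=fp.h)


def guler_step(
    state: GulerState,
    I: float,
    params: HHParameters,
    dt: float,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
    tau: float = 1.0,
) -> GulerState:
    """One Euler-Maruyama step (reference NumPy implementation).

    All drifts and noise amplitudes are evaluated at the start-of-step
    state; gating variables are clamped to [0, 1] after the update, and
    the voltage is advanced last from the updated state.
    """
    r = gate_rates(state.V)
    n, m, h = state.n, state.m, state.h
    fn = r.alpha_n * (1 - n) + r.beta_n * n
    fm = r.alpha_m * (1 - m) + r.beta_m * m
    fh = r.alpha_h * (1 - h) + r.beta_h * h
    z = rng.standard_normal(5)
    sq = np.sqrt(dt)

    n_new = n + dt * (r.alpha_n * (1 - n) - r.beta_n * n) + noise_scale * np.sqrt(fn / (4 * params.NK)) * sq * z[0]
    m_new = m + dt * (r.alpha_m * (1 - m) - r.beta_m * m) + noise_scale * np.sqrt(fm / (3 * params.NNa)) * sq * z[1]
    h_new = h + dt * (r.alpha_h * (1 - h) - r.beta_h * h) + noise_scale * np.sqrt(fh / params.NNa) * sq * z[2]
    qK_new = state.qK + dt * state.pK / tau
    pK_new = state.pK + dt * (-GAMMA_K * state.pK - OMEGA2_K * fn * state.qK) / tau \
        + noise_scale * np.sqrt(GAMMA_K * T_K * fn) * sq * z[3] / tau
    qNa_new = state.qNa + dt * state.pNa / tau
    pNa_new = state.pNa + dt * (-GAMMA_NA * state.pNa - OMEGA2_NA * fm * state.qNa) / tau \
        + noise_scale * np.sqrt(GAMMA_NA * T_NA * fm) * sq * z[4] / tau

    new = GulerState(
        V=state.V,
        n=min(max(n_new, 0.0), 1.0),
        m=min(max(m_new, 0.0), 1.0),
        h=min(max(h_new, 0.0), 1.0),
        qK=qK_new, pK=pK_new, qNa=qNa_new, pNa=pNa_new,
    )
    V_new = state.V + dt * (
        I
        - params.gK_max * psi_K(new, params.NK) * (state.V - params.VK)
        - params.gNa_max * psi_Na(new, params.NNa) * (state.V - params.VNa)
        - params.gL * (state.V - params.VL)
    ) / params.C
    return replace(new, V=float(V_new))


def simulate_guler(config: SimConfig) -> SimResult:
    """Simulate the oscillator-noise model, pooling ISIs over an ensemble.

    Trajectories start at the deterministic fixed point with gating at
    steady state and oscillator variables at zero; the first spike of
    each trajectory is discarded.
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
        seed = child_seed(config.seed, "guler", traj)
        spike_out = np.empty(capacity)
        if config.record_trace and traj == 0:
            n_rec = n_steps_max // config.trace_stride + 1
            rec_v = np.empty(n_rec)
            stride = config.trace_stride
        else:
            rec_v = np.empty(1)
            stride = 0
        status, n_spk, t_end, n_rec = _kernels.guler_core(
            seed, config.I, config.dt,
            params.gK_max, params.gNa_max, params.gL,
            params.VK, params.VNa, params.VL, params.C,
            params.NK, params.NNa,
            init.V, init.n, init.m, init.h,
            GAMMA_K, GAMMA_NA, OMEGA2_K, OMEGA2_NA, T_K, T_NA, config.tau,
            config.threshold, n_steps_max, max_spikes,
            config.noise_scale,
            spike_out, stride, rec_v,
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
        model="guler",
        spike_trains=spike_trains,
        isis=isis,
        t_total=t_total,
        manifest=config.manifest("guler"),
        trace=trace,
    )


register_simulator("guler", simulate_guler)
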