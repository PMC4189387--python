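"""Shared simulation config, results container, and channel-state helpers."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import comb
from typing import Callable

import numpy as np

from .params import HHParameters
from .rates import gate_rates


def child_seed(master: int, *keys) -> int:
    """Deterministic child seed from a master seed and arbitrary keys.

    String keys are hashed with crc32; the result is independent of the
    order in which other children are drawn, so ensemble members and
    sweep cells can run in any order.
    """
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=ints)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stationary_state_distribution(V: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-channel stationary law at clamped voltage ``V``.

    Gates are independent at fixed voltage, so the 5 potassium state
    probabilities are Binomial(4, p_n) and the 8 sodium state
    probabilities are Binomial(3, p_m) x Bernoulli(p_h), with
    p_x = alpha_x / (alpha_x + beta_x).
    """
    r = gate_rates(V)
    pn = r.alpha_n / (r.alpha_n + r.beta_n)
    pm = r.alpha_m / (r.alpha_m + r.beta_m)
    ph = r.alpha_h / (r.alpha_h + r.beta_h)
    pk = np.array([comb(4, i) * pn**i * (1 - pn) ** (4 - i) for i in range(5)])
    pna = np.empty(8)
    for j in range(4):
        for b in range(2):
            pna[2 * j + b] = comb(3, j) * pm**j * (1 - pm) ** (3 - j) * (ph if b else 1 - ph)
    return pk, pna


@dataclass(frozen=True)
class SimConfig:
    """Run configuration shared by all simulators.

    Exactly one stop rule must be set: ``duration`` (ms of simulated
    time) or ``target_isis`` (pooled ISI count across the ensemble).
    ``dt`` is the Euler-Maruyama step for the SDE models and the maximum
    voltage substep for the Markov-chain model.  ``tau`` is the time
    constant of the harmonic-oscillator variables (Güler model only).
    """

    I: float
    params: HHParameters = field(default_factory=HHParameters)
    dt: float = 0.005
    seed: int = 0
    duration: float | None = None
    target_isis: int | None = None
    ensemble: int = 1
    threshold: float = 0.0
    noise_scale: float = 1.0
    redraw_budget: int = 100
    record_trace: bool = False
    trace_stride: int = 10
    ms_per_spike_budget: float = 500.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if (self.duration is None) == (self.target_isis is None):
            raise ValueError("set exactly one of duration or target_isis")
        if self.ensemble < 1:
            raise ValueError("ensemble must be >= 1")

    def spikes_per_trajectory(self) -> int:
        """Spikes needed per trajectory under the ISI-count stop rule
        (the first spike of each trajectory is discarded)."""
        assert self.target_isis is not None
        per_isi = -(-self.target_isis // self.ensemble)  # ceil
        return per_isi + 2

    def manifest(self, model: str) -> dict:
        return {
            "model": model,
            "I": self.I,
            "area": self.params.area,
            "NK": self.params.NK,
            "NNa": self.params.NNa,
            "dt": self.dt,
            "seed": self.seed,
            "duration": self.duration,
            "target_isis": self.target_isis,
            "ensemble": self.ensemble,
            "threshold": self.threshold,
            "noise_scale": self.noise_scale,
            "redraw_budget": self.redraw_budget,
            "tau": self.tau,
        }


@dataclass
class SimResult:
    """Output of a (possibly ensemble) simulation run.

    ``spike_trains`` holds the raw per-trajectory spike times; ``isis``
    pools the inter-spike intervals after discarding each trajectory's
    first spike (transient removal).
    """

    model: str
    spike_trains: list[np.ndarray]
    isis: np.ndarray
    t_total: float
    manifest: dict
    trace: tuple[np.ndarray, np.ndarray] | None = None


def pool_isis(spike_trains: list[np.ndarray]) -> np.ndarray:
    parts = [np.diff(st[1:]) for st in spike_trains if len(st) >= 3]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


# Registry so further Langevin variants (e.g. the full matrix-square-root
# model or an Ornstein-Uhlenbeck conductance model) can plug in behind the
# same SimConfig -> SimResult contract.
SIMULATORS: dict[str, Callable[[SimConfig], SimResult]] = {}


def register_simulator(name: str, fn: Callable[[SimConfig], SimResult]) -> None:
    SIMULATORS[name] = fn


def get_simulator(name: str) -> Callable[[SimConfig], SimResult]:
    try:
        return SIMULATORS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(SIMULATORS)}"
        ) from None
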