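"""Synthetic ISI generators with known ground truth.

These emulate the three-part structure of the stochastic HH ISI
distribution — narrow initial peak, damped bump train, exponential tail —
with every component mass and parameter known in closed form, so the
feature-extraction pipeline can be calibrated against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ISIMixtureSpec", "generate_synthetic_isis", "generate_modulated_exponential"]


@dataclass(frozen=True)
class ISIMixtureSpec:
    """Three-component ISI mixture with closed-form component masses.

    peak: Gaussian at ``peak_loc`` (ms) with s.d. ``peak_width``.
    bumps: ``n_bumps`` Gaussians at peak_loc + k*bump_period (k = 1..n),
        weights proportional to exp(-bump_damping * (k-1)).
    tail: ``tail_start`` + Exponential(``tail_rate``); the default start
        lies inside the bump region, as in real ISI data, so the tail
        onset does not create a spurious local maximum.
    The three masses must sum to 1.
    """

    peak_mass: float = 0.6
    peak_loc: float = 15.0
    peak_width: float = 1.0
    bump_mass: float = 0.1
    bump_period: float = 12.0
    bump_damping: float = 1.0
    bump_width: float = 1.5
    n_bumps: int = 2
    tail_mass: float = 0.3
    tail_rate: float = 0.04
    tail_start: float = 25.0

    def __post_init__(self) -> None:
        total = self.peak_mass + self.bump_mass + self.tail_mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component masses must sum to 1, got {total}")
        if self.tail_rate <= 0 or self.peak_width <= 0:
            raise ValueError("tail_rate and peak_width must be positive")


def generate_synthetic_isis(
    spec: ISIMixtureSpec, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` ISIs from the mixture; returns (isis, component_labels)
    with labels 0 = peak, 1 = bumps, 2 = tail."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=[spec.peak_mass, spec.bump_mass, spec.tail_mass])
    out = np.empty(n)
    i_peak = labels == 0
    out[i_peak] = np.abs(rng.normal(spec.peak_loc, spec.peak_width, i_peak.sum()))
    i_bump = labels == 1
    if i_bump.any():
        w = np.exp(-spec.bump_damping * np.arange(spec.n_bumps))
        w /= w.sum()
        which = rng.choice(spec.n_bumps, size=i_bump.sum(), p=w)
        locs = spec.peak_loc + (which + 1) * spec.bump_period
        out[i_bump] = np.abs(rng.normal(locs, spec.bump_width))
    i_tail = labels == 2
    out[i_tail] = spec.tail_start + rng.exponential(1.0 / spec.tail_rate, i_tail.sum())
    return out, labels


def generate_modulated_exponential(
    rate: float,
    period: float,
    amplitude: float,
    n: int,
    seed: int = 0,
    t_offset: float = 0.0,
) -> np.ndarray:
    """Sample from density proportional to exp(-rate*t) * (1 + amplitude*cos(2*pi*t/period)).

    Rejection sampling against the plain exponential envelope; emulates a
    bump train of known period riding on an exponential tail.
    """
    if not (0.0 <= amplitude < 1.0):
        raise ValueError("amplitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = int((n - filled) * 2.5) + 16
        t = rng.exponential(1.0 / rate, m)
        accept = rng.random(m) < (1.0 + amplitude * np.cos(2 * np.pi * t / period)) / (1.0 + amplitude)
        good = t[accept]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out + t_offset
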