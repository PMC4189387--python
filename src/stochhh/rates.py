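"""Voltage-dependent gate transition rates of the Hodgkin-Huxley channels.

Each potassium channel carries four identical activation gates (``n``),
each sodium channel three activation gates (``m``) and one inactivation
gate (``h``).  A gate opens with rate ``alpha_x(V)`` and closes with rate
``beta_x(V)``; the six functions below are the classical squid-axon fits
in the modern voltage convention (rest near -65 mV).

``alpha_m`` and ``alpha_n`` have removable singularities (at V = -40 and
V = -55 respectively); they are evaluated through ``x/(1-exp(-x))`` with
an explicit series branch so the analytic limit is returned exactly.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class RateSet(NamedTuple):
    """The six gate transition rates (1/ms) at a single voltage."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float


def _xexprel(u):
    """u / (1 - exp(-u)), with the removable singularity at u = 0 filled in."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-7
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 + u / 2.0 + u * u / 12.0, safe / (-np.expm1(-safe)))
    return out


def _dxexprel(u):
    """Derivative of u / (1 - exp(-u))."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-5
    safe = np.where(small, 1.0, u)
    em = -np.expm1(-safe)  # 1 - exp(-u)
    out = np.where(
        small,
        0.5 + u / 6.0 - u**3 / 180.0,
        (em - safe * np.exp(-safe)) / (em * em),
    )
    return out


def gate_rates(V) -> RateSet:
    """Evaluate the six gate transition rates at voltage ``V`` (mV).

    Accepts a scalar or array; returns a :class:`RateSet` of matching
    shape.  All rates are non-negative and finite for finite ``V``.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    am = _xexprel((V + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    an = 0.1 * _xexprel((V + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    if V.ndim == 0:
        return RateSet(float(am), float(bm), float(ah), float(bh), float(an), float(bn))
    return RateSet(am, bm, ah, bh, an, bn)


def gate_rate_derivatives(V) -> RateSet:
    """d/dV of each transition rate, used for the analytic Jacobian."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    dam = _dxexprel((V + 40.0) / 10.0) / 10.0
    dbm = -4.0 * np.exp(-(V + 65.0) / 18.0) / 18.0
    dah = -0.07 * np.exp(-(V + 65.0) / 20.0) / 20.0
    s = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    dbh = s * (1.0 - s) / 10.0
    dan = 0.1 * _dxexprel((V + 55.0) / 10.0) / 10.0
    dbn = -0.125 * np.exp(-(V + 65.0) / 80.0) / 80.0
    if V.ndim == 0:
        return RateSet(float(dam), float(dbm), float(dah), float(dbh), float(dan), float(dbn))
    return RateSet(dam, dbm, dah, dbh, dan, dbn)


def steady_state_gating(V):
    """Equilibrium open probabilities (m_inf, h_inf, n_inf) at voltage ``V``."""
    r = gate_rates(V)
    return (
        r.alpha_m / (r.alpha_m + r.beta_m),
        r.alpha_h / (r.alpha_h + r.beta_h),
        r.alpha_n / (r.alpha_n + r.beta_n),
    )
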