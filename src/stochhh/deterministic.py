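"""Deterministic Hodgkin-Huxley dynamics and bifurcation landmarks.

The deterministic membrane is the 4-dimensional system (V, m, h, n) with

    C dV/dt = I - gNa_max m^3 h (V - VNa) - gK_max n^4 (V - VK) - gL (V - VL)

and first-order gating kinetics for m, h, n.  Over the current range
studied here (I = 0..12 uA/cm^2) the system has a unique fixed point
whose Jacobian carries one complex-conjugate eigenvalue pair (the
subthreshold oscillation, frequency omega) and two real negative
eigenvalues.  The fixed point loses stability in a subcritical Hopf
bifurcation near I = 9.8; sustained periodic spiking exists down to a
cycle-onset current near I = 6.26, so the two landmarks bracket a
bistable window in which quiescence and tonic spiking coexist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .params import HHParameters
from .rates import gate_rate_derivatives, gate_rates, steady_state_gating

__all__ = [
    "DeterministicState",
    "LinearizationResult",
    "deterministic_rhs",
    "find_fixed_point",
    "jacobian",
    "linearize",
    "find_hopf",
    "find_cycle_onset",
    "integrate",
    "spiking_initial_state",
]


@dataclass(frozen=True)
class DeterministicState:
    """Point in the deterministic phase space."""

    V: float
    m: float
    h: float
    n: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.V):
            raise ValueError("V must be finite")
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {x!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n])


@dataclass(frozen=True)
class LinearizationResult:
    """Fixed point and eigenstructure of the 4x4 Jacobian.

    ``lambda_re`` and ``omega`` are the real and imaginary parts of the
    complex-conjugate pair (1/ms and rad/ms); ``ev_slow`` and ``ev_fast``
    are the two real eigenvalues, ordered by magnitude.
    """

    fixed_point: DeterministicState
    lambda_re: float
    omega: float
    ev_slow: float
    ev_fast: float
    eigenvalues: np.ndarray

    @property
    def subthreshold_period(self) -> float:
        """Period of the subthreshold orbit, 2*pi/omega (ms)."""
        return 2.0 * np.pi / self.omega


def deterministic_rhs(state: DeterministicState, I: float, params: HHParameters) -> np.ndarray:
    """Time derivatives (dV/dt, dm/dt, dh/dt, dn/dt)."""
    V, m, h, n = state.V, state.m, state.h, state.n
    r = gate_rates(V)
    dV = (
        I
        - params.gNa_max * m**3 * h * (V - params.VNa)
        - params.gK_max * n**4 * (V - params.VK)
        - params.gL * (V - params.VL)
    ) / params.C
    dm = r.alpha_m * (1.0 - m) - r.beta_m * m
    dh = r.alpha_h * (1.0 - h) - r.beta_h * h
    dn = r.alpha_n * (1.0 - n) - r.beta_n * n
    return np.array([dV, dm, dh, dn])


def _current_balance(V: float, I: float, params: HHParameters) -> float:
    m, h, n = steady_state_gating(V)
    return (
        I
        - params.gNa_max * m**3 * h * (V - params.VNa)
        - params.gK_max * n**4 * (V - params.VK)
        - params.gL * (V - params.VL)
    )


def find_fixed_point(
    I: float, params: HHParameters | None = None, bracket: tuple[float, float] = (-90.0, -35.0)
) -> DeterministicState:
    """Fixed point of the deterministic system at applied current ``I``.

    The gating equations pin m, h, n to their steady-state curves, so the
    problem reduces to a scalar root of the current balance in V, solved
    by Brent's method on ``bracket``.
    """
    params = params or HHParameters()
    lo, hi = bracket
    flo = _current_balance(lo, I, params)
    fhi = _current_balance(hi, I, params)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change of the current balance on [{lo}, {hi}] "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g})"
        )
    V = brentq(_current_balance, lo, hi, args=(I, params), xtol=1e-13, rtol=1e-15)
    m, h, n = steady_state_gating(V)
    state = DeterministicState(V=float(V), m=float(m), h=float(h), n=float(n))
    residual = np.max(np.abs(deterministic_rhs(state, I, params)))
    if residual > 1e-10:
        raise RuntimeError(
            f"fixed-point residual {residual:.3g} exceeds 1e-10; last iterate {state}"
        )
    return state


def jacobian(state: DeterministicState, I: float, params: HHParameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of the vector field at ``state``."""
    V, m, h, n = state.V, state.m, state.h, state.n
    r = gate_rates(V)
    d = gate_rate_derivatives(V)
    gNa, gK, gL, C = params.gNa_max, params.gK_max, params.gL, params.C
    J = np.zeros((4, 4))
    J[0, 0] = -(gNa * m**3 * h + gK * n**4 + gL) / C
    J[0, 1] = -3.0 * gNa * m**2 * h * (V - params.VNa) / C
    J[0, 2] = -gNa * m**3 * (V - params.VNa) / C
    J[0, 3] = -4.0 * gK * n**3 * (V - params.VK) / C
    J[1, 0] = d.alpha_m * (1.0 - m) - d.beta_m * m
    J[1, 1] = -(r.alpha_m + r.beta_m)
    J[2, 0] = d.alpha_h * (1.0 - h) - d.beta_h * h
    J[2, 2] = -(r.alpha_h + r.beta_h)
    J[3, 0] = d.alpha_n * (1.0 - n) - d.beta_n * n
    J[3, 3] = -(r.alpha_n + r.beta_n)
    return J


def linearize(I: float, params: HHParameters | None = None) -> LinearizationResult:
    """Eigenstructure of the fixed-point Jacobian at current ``I``."""
    params = params or HHParameters()
    fp = find_fixed_point(I, params)
    ev = np.linalg.eigvals(jacobian(fp, I, params))
    cpx = ev[np.abs(ev.imag) > 1e-9]
    real = np.sort(ev[np.abs(ev.imag) <= 1e-9].real)
    if len(cpx) != 2 or len(real) != 2:
        raise RuntimeError(f"unexpected eigenvalue structure at I={I}: {ev}")
    return LinearizationResult(
        fixed_point=fp,
        lambda_re=float(cpx[0].real),
        omega=float(abs(cpx[0].imag)),
        ev_slow=float(real[1]),
        ev_fast=float(real[0]),
        eigenvalues=ev,
    )


def find_hopf(
    params: HHParameters | None = None, bracket: tuple[float, float] = (6.0, 12.0), xtol: float = 1e-4
) -> float:
    """Current at which the complex pair's real part crosses zero (Hopf)."""
    params = params or HHParameters()

    def lam_re(I: float) -> float:
        return linearize(I, params).lambda_re

    lo, hi = bracket
    if lam_re(lo) * lam_re(hi) > 0:
        raise RuntimeError(f"lambda_re does not change sign on [{lo}, {hi}]")
    return float(brentq(lam_re, lo, hi, xtol=xtol))


def integrate(
    I: float,
    duration: float,
    params: HHParameters | None = None,
    y0: DeterministicState | np.ndarray | None = None,
    dt: float = 0.01,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the deterministic system with fixed-step RK4.

    Returns ``(t, Y)`` with ``Y`` of shape (n_samples, 4), columns
    (V, m, h, n), sampled every ``stride`` steps.
    """
    params = params or HHParameters()
    if y0 is None:
        y0 = find_fixed_point(I, params)
    arr = y0.as_array() if isinstance(y0, DeterministicState) else np.asarray(y0, dtype=float)
    n_steps = int(round(duration / dt))
    Y = _kernels.det_rk4(
        arr, I, dt, n_steps, stride,
        params.gK_max, params.gNa_max, params.gL,
        params.VK, params.VNa, params.VL, params.C,
    )
    t = np.arange(Y.shape[0]) * dt * stride
    return t, Y


def spiking_initial_state(
    params: HHParameters | None = None, I_spike: float = 10.0, upstroke_level: float = -20.0
) -> DeterministicState:
    """A state on a spike upstroke, obtained from the tonically firing
    deterministic system at ``I_spike`` (where the fixed point is unstable).
    """
    params = params or HHParameters()
    fp = find_fixed_point(I_spike, params)
    y0 = fp.as_array()
    y0[0] += 5.0  # kick off the unstable fixed point
    t, Y = integrate(I_spike, 300.0, params, y0=y0, dt=0.01)
    V = Y[:, 0]
    up = np.nonzero((V[:-1] < upstroke_level) & (V[1:] >= upstroke_level))[0]
    # take a crossing late in the run, well onto the limit cycle
    if len(up) < 3:
        raise RuntimeError(f"no sustained spiking found at I={I_spike}")
    i = up[-1]
    m = min(max(Y[i, 1], 0.0), 1.0)
    h = min(max(Y[i, 2], 0.0), 1.0)
    n = min(max(Y[i, 3], 0.0), 1.0)
    return DeterministicState(V=float(V[i]), m=m, h=h, n=n)


def _spikes_in_window(V: np.ndarray, t: np.ndarray, t_from: float, threshold: float = 0.0) -> int:
    sel = t >= t_from
    v = V[sel]
    return int(np.count_nonzero((v[:-1] > threshold) & (v[1:] <= threshold)))


def sustained_spiking(
    I: float,
    params: HHParameters | None = None,
    y0: DeterministicState | None = None,
    transient: float = 1000.0,
    observe: float = 2000.0,
    dt: float = 0.01,
) -> bool:
    """Whether deterministic spiking persists in the final 1000 ms of a
    (transient + observe) run started from a spiking initial condition."""
    params = params or HHParameters()
    if y0 is None:
        y0 = spiking_initial_state(params)
    total = transient + observe
    t, Y = integrate(I, total, params, y0=y0, dt=dt, stride=5)
    return _spikes_in_window(Y[:, 0], t, total - 1000.0) >= 2


def find_cycle_onset(
    params: HHParameters | None = None,
    bracket: tuple[float, float] = (5.5, 7.0),
    resolution: float = 0.02,
    transient: float = 1000.0,
    observe: float = 2000.0,
    dt: float = 0.01,
) -> float:
    """Smallest current sustaining deterministic periodic spiking.

    Bisection on the sustained-spiking classifier, starting every trial
    from the same spike-upstroke state harvested at I = 10.
    """
    params = params or HHParameters()
    y0 = spiking_initial_state(params)
    lo, hi = bracket
    lo_spk = sustained_spiking(lo, params, y0, transient, observe, dt)
    hi_spk = sustained_spiking(hi, params, y0, transient, observe, dt)
    if lo_spk or not hi_spk:
        raise RuntimeError(
            f"bracket [{lo}, {hi}] does not straddle cycle onset "
            f"(spiking at ends: {lo_spk}, {hi_spk})"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if sustained_spiking(mid, params, y0, transient, observe, dt):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
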