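"""Numba-compiled integration kernels.

These are the hot loops behind the public simulators: a fixed-step RK4
integrator for the deterministic membrane, Euler-Maruyama loops for the
two Langevin models, and the hybrid Gillespie loop for the exact
channel-state Markov chain.  All randomness comes from numba's
``np.random`` seeded once per trajectory, so every trajectory is fully
reproducible from its integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Undirected transition edges of the 8-state sodium network, Table layout
# s0=m0h0, s1=m0h1, s2=m1h0, s3=m1h1, s4=m2h0, s5=m2h1, s6=m3h0, s7=m3h1.
# The first six edges are m-gate edges (fwd rate mult*alpha_m, bwd rate
# mult*beta_m); the last four are h-gate edges (alpha_h / beta_h).
NA_EDGE_A = np.array([0, 2, 4, 1, 3, 5, 0, 2, 4, 6], dtype=np.int64)
NA_EDGE_B = np.array([2, 4, 6, 3, 5, 7, 1, 3, 5, 7], dtype=np.int64)
NA_FWD_MULT = np.array([3, 2, 1, 3, 2, 1, 0, 0, 0, 0], dtype=np.int64)
NA_BWD_MULT = np.array([1, 2, 3, 1, 2, 3, 0, 0, 0, 0], dtype=np.int64)

# Status codes shared by the stochastic kernels.
OK = 0
REDRAW_EXHAUSTED = 1
BUDGET_EXCEEDED = 2


@njit(cache=True)
def rates_scalar(V):
    """Six gate rates at scalar voltage; series branch at the singularities."""
    u = (V + 40.0) / 10.0
    if abs(u) < 1e-7:
        am = 1.0 + 0.5 * u
    else:
        am = u / (1.0 - np.exp(-u))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    w = (V + 55.0) / 10.0
    if abs(w) < 1e-7:
        an = 0.1 * (1.0 + 0.5 * w)
    else:
        an = 0.1 * w / (1.0 - np.exp(-w))
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _det_rhs(V, m, h, n, I, gK, gNa, gL, VK, VNa, VL, C):
    am, bm, ah, bh, an, bn = rates_scalar(V)
    dV = (I - gNa * m**3 * h * (V - VNa) - gK * n**4 * (V - VK) - gL * (V - VL)) / C
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dV, dm, dh, dn


@njit(cache=True)
def det_rk4(y0, I, dt, n_steps, stride, gK, gNa, gL, VK, VNa, VL, C):
    """Fixed-step RK4 for the deterministic HH system.

    Returns a (n_rec, 4) array of the state sampled every ``stride``
    steps, with the initial state in row 0.
    """
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 4))
    V, m, h, n = y0[0], y0[1], y0[2], y0[3]
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = V, m, h, n
    r = 1
    for step in range(1, n_steps + 1):
        k1 = _det_rhs(V, m, h, n, I, gK, gNa, gL, VK, VNa, VL, C)
        k2 = _det_rhs(
            V + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1],
            h + 0.5 * dt * k1[2], n + 0.5 * dt * k1[3],
            I, gK, gNa, gL, VK, VNa, VL, C,
        )
        k3 = _det_rhs(
            V + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1],
            h + 0.5 * dt * k2[2], n + 0.5 * dt * k2[3],
            I, gK, gNa, gL, VK, VNa, VL, C,
        )
        k4 = _det_rhs(
            V + dt * k3[0], m + dt * k3[1], h + dt * k3[2], n + dt * k3[3],
            I, gK, gNa, gL, VK, VNa, VL, C,
        )
        V += dt * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0]) / 6.0
        m += dt * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]) / 6.0
        h += dt * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]) / 6.0
        n += dt * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3]) / 6.0
        if step % stride == 0:
            out[r, 0], out[r, 1], out[r, 2], out[r, 3] = V, m, h, n
            r += 1
    return out[:r]


@njit(cache=True)
def orio_core(
    seed, I, dt,
    gK, gNa, gL, VK, VNa, VL, C,
    NK, NNa,
    V0, k0, s0,
    thr, n_steps_max, max_spikes,
    noise_scale, redraw_budget,
    spike_out,
    rec_stride, rec_v,
):
    """Euler-Maruyama loop for the 13-SDE shared-edge-noise Langevin model.

    Per step: update the 5 potassium and 8 sodium state fractions with one
    Gaussian draw per transition edge (4 + 10 edges); a negative potassium
    fraction triggers a full redraw of that chain's noises, a negative
    sodium fraction is reset to zero; both chains are then renormalized to
    sum 1; finally the voltage is advanced by Euler with conductances
    gK*n4, gNa*s7.  Spike times (downward threshold crossings, linearly
    interpolated) go to ``spike_out``.

    Returns (status, n_spikes, t_end, n_recorded).
    """
    np.random.seed(seed)
    k = k0.copy()
    s = s0.copy()
    V = V0
    sqdt = np.sqrt(dt)
    n_spk = 0
    t = 0.0
    n_rec = 0
    if rec_stride > 0:
        rec_v[0] = V
        n_rec = 1
    drift_k = np.empty(5)
    new_k = np.empty(5)
    amp_k = np.empty(4)
    drift_s = np.empty(8)
    for step in range(n_steps_max):
        am, bm, ah, bh, an, bn = rates_scalar(V)

        # --- potassium chain: 5 states, 4 edges, shared edge noises
        for i in range(5):
            drift_k[i] = 0.0
        for j in range(4):
            ffwd = (4.0 - j) * an * k[j]
            fbwd = (j + 1.0) * bn * k[j + 1]
            net = ffwd - fbwd
            drift_k[j] -= net
            drift_k[j + 1] += net
            amp_k[j] = noise_scale * np.sqrt((ffwd + fbwd) / NK) * sqdt
        ok = False
        for _ in range(redraw_budget):
            for i in range(5):
                new_k[i] = k[i] + dt * drift_k[i]
            for j in range(4):
                z = np.random.normal()
                new_k[j] -= amp_k[j] * z
                new_k[j + 1] += amp_k[j] * z
            neg = False
            for i in range(5):
                if new_k[i] < 0.0:
                    neg = True
                    break
            if not neg:
                ok = True
                break
        if not ok:
            return REDRAW_EXHAUSTED, n_spk, t, n_rec
        tot = 0.0
        for i in range(5):
            tot += new_k[i]
        for i in range(5):
            k[i] = new_k[i] / tot

        # --- sodium chain: 8 states, 10 edges
        for i in range(8):
            drift_s[i] = 0.0
        for e in range(10):
            a = NA_EDGE_A[e]
            b = NA_EDGE_B[e]
            if NA_FWD_MULT[e] > 0:
                fa = NA_FWD_MULT[e] * am
                fb = NA_BWD_MULT[e] * bm
            else:
                fa = ah
                fb = bh
            ffwd = fa * s[a]
            fbwd = fb * s[b]
            net = ffwd - fbwd
            drift_s[a] -= net
            drift_s[b] += net
            amp = noise_scale * np.sqrt((ffwd + fbwd) / NNa) * sqdt
            z = np.random.normal()
            drift_s[a] -= amp * z / dt
            drift_s[b] += amp * z / dt
        tot = 0.0
        for i in range(8):
            v = s[i] + dt * drift_s[i]
            if v < 0.0:
                v = 0.0
            s[i] = v
            tot += v
        for i in range(8):
            s[i] /= tot

        # --- voltage, after the channel step (protocol order)
        Vprev = V
        V += dt * (I - gNa * s[7] * (V - VNa) - gK * k[4] * (V - VK) - gL * (V - VL)) / C
        t += dt
        if Vprev > thr and V <= thr:
            t_sp = t - dt + dt * (Vprev - thr) / (Vprev - V)
            if n_spk < spike_out.shape[0]:
                spike_out[n_spk] = t_sp
            n_spk += 1
            if max_spikes > 0 and n_spk >= max_spikes:
                if rec_stride > 0 and (step + 1) % rec_stride == 0 and n_rec < rec_v.shape[0]:
                    rec_v[n_rec] = V
                    n_rec += 1
                return OK, n_spk, t, n_rec
        if rec_stride > 0 and (step + 1) % rec_stride == 0 and n_rec < rec_v.shape[0]:
            rec_v[n_rec] = V
            n_rec += 1
    if max_spikes > 0:
        return BUDGET_EXCEEDED, n_spk, t, n_rec
    return OK, n_spk, t, n_rec


@njit(cache=True)
def guler_core(
    seed, I, dt,
    gK, gNa, gL, VK, VNa, VL, C,
    NK, NNa,
    V0, n0, m0, h0,
    gammaK, gammaNa, om2K, om2Na, TK, TNa, tau,
    thr, n_steps_max, max_spikes,
    noise_scale,
    spike_out,
    rec_stride, rec_v,
):
    """Euler-Maruyama loop for the 7-SDE harmonic-oscillator Langevin model.

    State: (V, n, m, h, qK, pK, qNa, pNa).  The oscillator pairs (qK, pK)
    and (qNa, pNa) modulate the open-channel fractions psiK = n^4 +
    sqrt(n^4(1-n^4)/NK) qK and psiNa = m^3 h + sqrt(m^3(1-m^3)/NNa) h qNa.
    Gating variables are clamped to [0, 1] after each step.

    Returns (status, n_spikes, t_end, n_recorded).
    """
    np.random.seed(seed)
    V = V0
    n = n0
    m = m0
    h = h0
    qK = 0.0
    pK = 0.0
    qNa = 0.0
    pNa = 0.0
    sqdt = np.sqrt(dt)
    n_spk = 0
    t = 0.0
    n_rec = 0
    if rec_stride > 0:
        rec_v[0] = V
        n_rec = 1
    for step in range(n_steps_max):
        am, bm, ah, bh, an, bn = rates_scalar(V)
        fn = an * (1.0 - n) + bn * n
        fm = am * (1.0 - m) + bm * m
        fh = ah * (1.0 - h) + bh * h

        dn = dt * (an * (1.0 - n) - bn * n) + noise_scale * np.sqrt(fn / (4.0 * NK)) * sqdt * np.random.normal()
        dm = dt * (am * (1.0 - m) - bm * m) + noise_scale * np.sqrt(fm / (3.0 * NNa)) * sqdt * np.random.normal()
        dh = dt * (ah * (1.0 - h) - bh * h) + noise_scale * np.sqrt(fh / NNa) * sqdt * np.random.normal()
        dqK = dt * pK / tau
        dpK = dt * (-gammaK * pK - om2K * fn * qK) / tau + noise_scale * np.sqrt(gammaK * TK * fn) * sqdt * np.random.normal() / tau
        dqNa = dt * pNa / tau
        dpNa = dt * (-gammaNa * pNa - om2Na * fm * qNa) / tau + noise_scale * np.sqrt(gammaNa * TNa * fm) * sqdt * np.random.normal() / tau

        n += dn
        m += dm
        h += dh
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        qK += dqK
        pK += dpK
        qNa += dqNa
        pNa += dpNa

        n4 = n**4
        m3 = m**3
        psiK = n4 + np.sqrt(n4 * (1.0 - n4) / NK) * qK
        psiNa = m3 * h + np.sqrt(m3 * (1.0 - m3) / NNa) * h * qNa
        Vprev = V
        V += dt * (I - gK * psiK * (V - VK) - gNa * psiNa * (V - VNa) - gL * (V - VL)) / C
        t += dt
        if Vprev > thr and V <= thr:
            t_sp = t - dt + dt * (Vprev - thr) / (Vprev - V)
            if n_spk < spike_out.shape[0]:
                spike_out[n_spk] = t_sp
            n_spk += 1
            if max_spikes > 0 and n_spk >= max_spikes:
                if rec_stride > 0 and (step + 1) % rec_stride == 0 and n_rec < rec_v.shape[0]:
                    rec_v[n_rec] = V
                    n_rec += 1
                return OK, n_spk, t, n_rec
        if rec_stride > 0 and (step + 1) % rec_stride == 0 and n_rec < rec_v.shape[0]:
            rec_v[n_rec] = V
            n_rec += 1
    if max_spikes > 0:
        return BUDGET_EXCEEDED, n_spk, t, n_rec
    return OK, n_spk, t, n_rec


@njit(cache=True)
def micro_propensities(k, s, V, props):
    """Fill the 28 directed-edge propensities (8 K edges then 20 Na edges).

    Edge order: K j->j+1 (j=0..3), K j+1->j (j=0..3), then for each of the
    10 undirected Na edges its forward then backward direction.
    Returns the total propensity.
    """
    am, bm, ah, bh, an, bn = rates_scalar(V)
    tot = 0.0
    for j in range(4):
        props[j] = (4.0 - j) * an * k[j]
        props[4 + j] = (j + 1.0) * bn * k[j + 1]
        tot += props[j] + props[4 + j]
    for e in range(10):
        a = NA_EDGE_A[e]
        b = NA_EDGE_B[e]
        if NA_FWD_MULT[e] > 0:
            fa = NA_FWD_MULT[e] * am
            fb = NA_BWD_MULT[e] * bm
        else:
            fa = ah
            fb = bh
        props[8 + 2 * e] = fa * s[a]
        props[8 + 2 * e + 1] = fb * s[b]
        tot += props[8 + 2 * e] + props[8 + 2 * e + 1]
    return tot


@njit(cache=True)
def micro_core(
    seed, I, dt_max,
    gK, gNa, gL, VK, VNa, VL, C,
    NK, NNa,
    V0, k0, s0,
    thr, t_max, max_spikes,
    clamp, guard, event_budget,
    spike_out,
    occ_k, occ_na,
):
    """Hybrid Gillespie loop for the exact channel-state Markov chain.

    Channel counts are integers; one transition fires per event.  Between
    events the voltage is advanced by Euler substeps of at most ``dt_max``
    with counts frozen; if the total propensity drifts by more than
    ``guard`` (relative) during the waiting time, the pending event is
    abandoned and redrawn from the current state (memorylessness makes
    this exact to first order).  With ``clamp`` true, the voltage is held
    at ``V0`` and time-weighted state occupancies are accumulated into
    ``occ_k`` / ``occ_na``.

    Returns (status, n_spikes, t_end, n_events, conservation_violations).
    """
    np.random.seed(seed)
    k = k0.copy()
    s = s0.copy()
    V = V0
    t = 0.0
    n_spk = 0
    n_events = 0
    violations = 0
    props = np.empty(28)
    while t < t_max - 1e-12:
        if max_spikes > 0 and n_spk >= max_spikes:
            break
        if n_events >= event_budget:
            return BUDGET_EXCEEDED, n_spk, t, n_events, violations
        R0 = micro_propensities(k, s, V, props)
        tau = -np.log(np.random.random()) / R0
        truncated_end = False
        if tau > t_max - t:
            tau = t_max - t
            truncated_end = True

        if clamp:
            for i in range(5):
                occ_k[i] += k[i] * tau
            for i in range(8):
                occ_na[i] += s[i] * tau
            t += tau
        else:
            # advance V over tau with counts frozen, guarding propensity drift
            remaining = tau
            aborted = False
            while remaining > 0.0:
                hstep = dt_max if dt_max < remaining else remaining
                Vprev = V
                V += hstep * (
                    I
                    - gNa * (s[7] / NNa) * (V - VNa)
                    - gK * (k[4] / NK) * (V - VK)
                    - gL * (V - VL)
                ) / C
                t += hstep
                remaining -= hstep
                if Vprev > thr and V <= thr:
                    t_sp = t - hstep + hstep * (Vprev - thr) / (Vprev - V)
                    if n_spk < spike_out.shape[0]:
                        spike_out[n_spk] = t_sp
                    n_spk += 1
                    if max_spikes > 0 and n_spk >= max_spikes:
                        return OK, n_spk, t, n_events, violations
                R1 = micro_propensities(k, s, V, props)
                if abs(R1 - R0) > guard * R0:
                    aborted = True
                    break
            if aborted or truncated_end:
                continue

        if truncated_end:
            break

        # choose and apply one transition, propensities at the current V
        R = micro_propensities(k, s, V, props)
        u = np.random.random() * R
        acc = 0.0
        edge = 27
        for e in range(28):
            acc += props[e]
            if u < acc:
                edge = e
                break
        if edge < 4:
            k[edge] -= 1
            k[edge + 1] += 1
        elif edge < 8:
            j = edge - 4
            k[j + 1] -= 1
            k[j] += 1
        else:
            e = (edge - 8) // 2
            a = NA_EDGE_A[e]
            b = NA_EDGE_B[e]
            if (edge - 8) % 2 == 0:
                s[a] -= 1
                s[b] += 1
            else:
                s[b] -= 1
                s[a] += 1
        n_events += 1
        tk = 0
        for i in range(5):
            tk += k[i]
        ts = 0
        for i in range(8):
            ts += s[i]
        if tk != NK or ts != NNa:
            violations += 1
    return OK, n_spk, t, n_events, violations
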