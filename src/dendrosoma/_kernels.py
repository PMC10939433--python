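"""Compiled fixed-step integrators for Morris-Lecar somas with passive cables.

These kernels exist because the phase-response and network protocols need
hundreds of seconds of biological time at sub-0.05 ms steps; they implement
classical RK4 with on-the-fly threshold-crossing spike detection (linearly
interpolated spike times) and support a single voltage perturbation (for
PRCs) or impulse synaptic coupling (for networks).

State layout per neuron: ``[v_sigma, w, v_delta[0..M-1]]`` with M = 0 for the
instantaneous-cable (point-model) limit.  The parameter vector is

    p = [C, G_L, E_L, G_Ca, E_Ca, G_K, E_K, V1, V2, V3, V4, phi,
         rho, tau_delta, h]

with h the electrotonic compartment length.  The explicit scheme is stable
for dt below ~2.78 tau_delta / (4 (1/h)^2 + 1); callers are expected to pass
a dt respecting that bound (see :func:`dendrosoma.dynamics.default_dt`).
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_single", "run_network", "run_graph"]


@njit(cache=True)
def _rhs(y, dy, p, I_ext):
    C, GL, EL = p[0], p[1], p[2]
    GCa, ECa, GK, EK = p[3], p[4], p[5], p[6]
    V1, V2, V3, V4, phi = p[7], p[8], p[9], p[10], p[11]
    rho, td, h = p[12], p[13], p[14]
    v = y[0]
    w = y[1]
    minf = 0.5 * (1.0 + np.tanh((v - V1) / V2))
    winf = 0.5 * (1.0 + np.tanh((v - V3) / V4))
    tw = 1.0 / (phi * np.cosh((v - V3) / (2.0 * V4)))
    dv = (GL * (EL - v) + GCa * minf * (ECa - v) + GK * w * (EK - v) + I_ext) / C
    M = y.shape[0] - 2
    if M > 0:
        c = 1.0 / (h * h)
        g_ax = 2.0 * rho * GL / h
        dv += g_ax * (y[2] - v) / C
        for i in range(M):
            vi = y[2 + i]
            lap = 0.0
            if i == 0:
                lap += 2.0 * c * (v - vi)
                if M > 1:
                    lap += c * (y[3] - vi)
            elif i == M - 1:
                lap += c * (y[1 + i] - vi)
            else:
                lap += c * (y[3 + i] - 2.0 * vi + y[1 + i])
            dy[2 + i] = (EL - vi + lap) / td
    dy[0] = dv
    dy[1] = (winf - w) / tw


@njit(cache=True)
def _rk4_step(y, p, I_ext, dt, k1, k2, k3, k4, tmp):
    n = y.shape[0]
    _rhs(y, k1, p, I_ext)
    for i in range(n):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    _rhs(tmp, k2, p, I_ext)
    for i in range(n):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    _rhs(tmp, k3, p, I_ext)
    for i in range(n):
        tmp[i] = y[i] + dt * k3[i]
    _rhs(tmp, k4, p, I_ext)
    for i in range(n):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def run_single(y0, p, I_ext, T, dt, threshold, pert_time, pert_dv,
               record_stride, max_spikes):
    """Integrate one neuron for time T.

    ``pert_time >= 0`` applies an instantaneous voltage step ``pert_dv`` to
    the soma at the first step boundary at or after that time.  With
    ``record_stride > 0`` the somatic voltage is sampled every that many
    steps.  Returns (spike_times, n_spikes, y_final, v_trace).
    """
    y = y0.copy()
    n_steps = int(np.ceil(T / dt))
    k1 = np.empty_like(y); k2 = np.empty_like(y)
    k3 = np.empty_like(y); k4 = np.empty_like(y); tmp = np.empty_like(y)
    spikes = np.empty(max_spikes)
    n_sp = 0
    n_rec = n_steps // record_stride + 1 if record_stride > 0 else 0
    trace = np.empty(n_rec)
    i_rec = 0
    perturbed = pert_time < 0.0
    t = 0.0
    for k in range(n_steps):
        if not perturbed and t >= pert_time:
            if y[0] < threshold <= y[0] + pert_dv and n_sp < max_spikes:
                spikes[n_sp] = t  # the step itself crosses threshold
                n_sp += 1
            y[0] += pert_dv
            perturbed = True
        if record_stride > 0 and k % record_stride == 0 and i_rec < n_rec:
            trace[i_rec] = y[0]
            i_rec += 1
        v_prev = y[0]
        _rk4_step(y, p, I_ext, dt, k1, k2, k3, k4, tmp)
        t += dt
        if v_prev < threshold <= y[0] and n_sp < max_spikes:
            frac = (threshold - v_prev) / (y[0] - v_prev)
            spikes[n_sp] = t - dt + frac * dt
            n_sp += 1
    return spikes[:n_sp], n_sp, y, trace[:i_rec]


@njit(cache=True)
def run_network(Y0, p, I_ext, W, T, dt, threshold, max_spikes):
    """Integrate N identical neurons with impulse (voltage-jump) coupling.

    ``W[i, j]`` is the somatic voltage jump applied to neuron i when neuron j
    spikes (zero transmission delay: the jump lands at the end of the step in
    which the presynaptic upward threshold crossing occurs).  Returns
    (spike_times, spike_neuron, n_spikes, Y_final).
    """
    N, n = Y0.shape
    Y = Y0.copy()
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); tmp = np.empty(n)
    sp_t = np.empty(max_spikes)
    sp_i = np.empty(max_spikes, dtype=np.int64)
    n_sp = 0
    fired = np.zeros(N, dtype=np.bool_)
    n_steps = int(np.ceil(T / dt))
    t = 0.0
    queue = np.empty(N, dtype=np.int64)
    for k in range(n_steps):
        for i in range(N):
            fired[i] = False
        n_q = 0
        for i in range(N):
            v_prev = Y[i, 0]
            _rk4_step(Y[i], p, I_ext[i], dt, k1, k2, k3, k4, tmp)
            if v_prev < threshold <= Y[i, 0]:
                fired[i] = True
                queue[n_q] = i
                n_q += 1
                if n_sp < max_spikes:
                    frac = (threshold - v_prev) / (Y[i, 0] - v_prev)
                    sp_t[n_sp] = t + frac * dt
                    sp_i[n_sp] = i
                    n_sp += 1
        # propagate impulses; a jump can itself push a neuron over threshold
        # (cascade bounded: each neuron fires at most once per step)
        head = 0
        while head < n_q:
            j = queue[head]
            head += 1
            for i in range(N):
                if i != j:
                    v_prev = Y[i, 0]
                    Y[i, 0] += W[i, j]
                    if (not fired[i]) and v_prev < threshold <= Y[i, 0]:
                        fired[i] = True
                        queue[n_q] = i
                        n_q += 1
                        if n_sp < max_spikes:
                            sp_t[n_sp] = t + dt
                            sp_i[n_sp] = i
                            n_sp += 1
        t += dt
    return sp_t[:n_sp], sp_i[:n_sp], n_sp, Y


@njit(cache=True)
def _graph_rhs(y, dy, psoma, leak_rate, indptr, indices, weights,
               soma_idx, soma_w, EL, I_ext):
    """Morris-Lecar soma coupled to an arbitrary passive compartment graph.

    ``weights[k]`` is the axial rate a_jk / c_j (1/ms) for the edge stored at
    position k of row j; ``soma_idx``/``soma_w`` list the compartments
    touching the soma and their conductance-over-C_sigma rates.
    """
    C, GL = psoma[0], psoma[1]
    GCa, ECa, GK, EK = psoma[3], psoma[4], psoma[5], psoma[6]
    V1, V2, V3, V4, phi = psoma[7], psoma[8], psoma[9], psoma[10], psoma[11]
    v = y[0]
    w = y[1]
    minf = 0.5 * (1.0 + np.tanh((v - V1) / V2))
    winf = 0.5 * (1.0 + np.tanh((v - V3) / V4))
    tw = 1.0 / (phi * np.cosh((v - V3) / (2.0 * V4)))
    dv = (GL * (EL - v) + GCa * minf * (ECa - v) + GK * w * (EK - v) + I_ext) / C
    for k in range(soma_idx.shape[0]):
        dv += soma_w[k] * (y[2 + soma_idx[k]] - v)
    dy[0] = dv
    dy[1] = (winf - w) / tw
    n_c = y.shape[0] - 2
    for j in range(n_c):
        vj = y[2 + j]
        acc = leak_rate[j] * (EL - vj)
        for k in range(indptr[j], indptr[j + 1]):
            m = indices[k]
            vother = v if m == -1 else y[2 + m]
            acc += weights[k] * (vother - vj)
        dy[2 + j] = acc


@njit(cache=True)
def run_graph(y0, psoma, leak_rate, indptr, indices, weights, soma_idx,
              soma_w, EL, I_ext, T, dt, threshold, pert_time, pert_dv,
              max_spikes):
    """RK4 on the soma + compartment-graph system; same contract as run_single."""
    y = y0.copy()
    n = y.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); tmp = np.empty(n)
    spikes = np.empty(max_spikes)
    n_sp = 0
    n_steps = int(np.ceil(T / dt))
    perturbed = pert_time < 0.0
    t = 0.0
    for step in range(n_steps):
        if not perturbed and t >= pert_time:
            y[0] += pert_dv
            perturbed = True
        v_prev = y[0]
        _graph_rhs(y, k1, psoma, leak_rate, indptr, indices, weights,
                   soma_idx, soma_w, EL, I_ext)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _graph_rhs(tmp, k2, psoma, leak_rate, indptr, indices, weights,
                   soma_idx, soma_w, EL, I_ext)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _graph_rhs(tmp, k3, psoma, leak_rate, indptr, indices, weights,
                   soma_idx, soma_w, EL, I_ext)
        for i in range(n):
            tmp[i] = y[i] + dt * k3[i]
        _graph_rhs(tmp, k4, psoma, leak_rate, indptr, indices, weights,
                   soma_idx, soma_w, EL, I_ext)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        t += dt
        if v_prev < threshold <= y[0] and n_sp < max_spikes:
            frac = (threshold - v_prev) / (y[0] - v_prev)
            spikes[n_sp] = t - dt + frac * dt
            n_sp += 1
    return spikes[:n_sp], n_sp, y
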