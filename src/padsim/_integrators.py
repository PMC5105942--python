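"""Numba-jitted fixed-step integrators.

Two kernels live here:

* ``rk4_single`` — classical RK4 for the 3-state single-compartment model.
  The stimulus (total synaptic conductance, conductance-weighted reversal
  sum, injected current) is pre-sampled on the half-step grid so the kernel
  never touches Python objects.
* ``cable_step_implicit`` — Rush-Larsen gating update plus a linearly
  implicit (backward-Euler) voltage step with a Thomas tridiagonal solve for
  the axial coupling.  Unconditionally stable in the diffusive part, which
  matters because the d_lambda rule at 0.01 yields segments ~1.6 um long.

Parameter packing (see NeuronParams.to_array): [C, gNa, ENa, beta_m, gamma_m,
gK, EK, phi_w, beta_w, gamma_w, g_leak, E_leak, p, beta_h, gamma_h, phi_h,
g_Na_virtual(mS/cm^2)].
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter indices
(_C, _GNA, _ENA, _BM, _GM, _GK, _EK, _PHIW, _BW, _GW, _GL, _EL, _P, _BH,
 _GH, _PHIH, _GNAV, _BMV, _GMV) = range(19)


@njit(cache=True, inline="always")
def _rhs(V, w, h, pr, g_syn, ge_syn, i_stim, out):
    m_inf = 0.5 * (1.0 + np.tanh((V - pr[_BM]) / pr[_GM]))
    m_inf_v = 0.5 * (1.0 + np.tanh((V - pr[_BMV]) / pr[_GMV]))
    na_open = (1.0 - pr[_P]) + pr[_P] * h
    i_na = (pr[_GNA] * na_open * m_inf + pr[_GNAV] * m_inf_v) * (V - pr[_ENA])
    i_k = pr[_GK] * w * (V - pr[_EK])
    i_leak = pr[_GL] * (V - pr[_EL])
    # g_syn*(V - E) summed over inputs = (sum g)*V - (sum g*E)
    i_gaba = g_syn * V - ge_syn
    out[0] = (i_stim - i_na - i_k - i_leak - i_gaba) / pr[_C]
    uw = (V - pr[_BW]) / (2.0 * pr[_GW])
    w_inf = 0.5 * (1.0 + np.tanh((V - pr[_BW]) / pr[_GW]))
    out[1] = pr[_PHIW] * (w_inf - w) * np.cosh(uw)
    uh = (V - pr[_BH]) / (2.0 * pr[_GH])
    h_inf = 0.5 * (1.0 + np.tanh((V - pr[_BH]) / pr[_GH]))
    out[2] = pr[_PHIH] * (h_inf - h) * np.cosh(uh)


@njit(cache=True)
def rk4_single(pr, g_half, ge_half, i_half, dt, n_steps, v0, w0, h0, stride):
    """Integrate n_steps of RK4; record every ``stride``-th state.

    ``g_half``/``ge_half``/``i_half`` are sampled at t = 0, dt/2, dt, ...
    (length 2*n_steps + 1).  Returns (V, w, h) arrays of length
    n_steps//stride + 1 and a status flag (0 ok, else the step index where
    the state went non-finite).
    """
    n_out = n_steps // stride + 1
    V_out = np.empty(n_out)
    w_out = np.empty(n_out)
    h_out = np.empty(n_out)
    V, w, h = v0, w0, h0
    V_out[0], w_out[0], h_out[0] = V, w, h
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    status = 0
    for n in range(n_steps):
        i0 = 2 * n
        _rhs(V, w, h, pr, g_half[i0], ge_half[i0], i_half[i0], k1)
        _rhs(
            V + 0.5 * dt * k1[0], w + 0.5 * dt * k1[1], h + 0.5 * dt * k1[2],
            pr, g_half[i0 + 1], ge_half[i0 + 1], i_half[i0 + 1], k2,
        )
        _rhs(
            V + 0.5 * dt * k2[0], w + 0.5 * dt * k2[1], h + 0.5 * dt * k2[2],
            pr, g_half[i0 + 1], ge_half[i0 + 1], i_half[i0 + 1], k3,
        )
        _rhs(
            V + dt * k3[0], w + dt * k3[1], h + dt * k3[2],
            pr, g_half[i0 + 2], ge_half[i0 + 2], i_half[i0 + 2], k4,
        )
        V += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        w += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        h += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        if not (np.isfinite(V) and np.isfinite(w) and np.isfinite(h)):
            status = n + 1
            break
        if (n + 1) % stride == 0:
            j = (n + 1) // stride
            V_out[j], w_out[j], h_out[j] = V, w, h
    return V_out, w_out, h_out, status


@njit(cache=True)
def cable_integrate(
    pr,
    axial,            # uA/cm^2 per mV coupling coefficient between neighbours
    gg_mask,          # per-segment GABA density mask (mS/cm^2 at unit shape)
    e_gaba,
    g_shape,          # GABA time course, per step (length n_steps + 1)
    i_shape,          # injected current time course (uA/cm^2), per step
    i_mask,           # per-segment current mask (1.0 on injected segments)
    dt,
    n_steps,
    V0, w0, h0,       # initial per-segment state
    stride,
    rec_idx,          # indices of recorded segments
    theta,            # 1.0 = backward Euler, 0.5 = Crank-Nicolson
):
    """Semi-implicit integration of the multicompartment cable.

    Gating: Rush-Larsen exact exponential update.  Voltage: theta-method
    (Crank-Nicolson at theta = 0.5) with conductances frozen over the step,
    giving a symmetric tridiagonal system solved by the Thomas algorithm.
    Sealed ends.  Returns per-recorded-segment V traces and a status flag.
    """
    n = V0.shape[0]
    n_rec = rec_idx.shape[0]
    n_out = n_steps // stride + 1
    V_rec = np.empty((n_rec, n_out))
    V = V0.copy()
    w = w0.copy()
    h = h0.copy()
    for r in range(n_rec):
        V_rec[r, 0] = V[rec_idx[r]]
    # Thomas workspace
    a = np.empty(n)   # sub/super diagonal (constant: -axial)
    b = np.empty(n)   # main diagonal
    d = np.empty(n)   # rhs
    cp = np.empty(n)
    dp = np.empty(n)
    status = 0
    C = pr[_C]
    for step in range(n_steps):
        t1 = step + 1
        gs = g_shape[t1]
        i_inj = i_shape[t1]
        for i in range(n):
            Vi = V[i]
            # Rush-Larsen gating update using V at start of step
            uw = (Vi - pr[_BW]) / (2.0 * pr[_GW])
            w_inf = 0.5 * (1.0 + np.tanh((Vi - pr[_BW]) / pr[_GW]))
            kw = pr[_PHIW] * np.cosh(uw)
            w[i] = w_inf + (w[i] - w_inf) * np.exp(-dt * kw)
            uh = (Vi - pr[_BH]) / (2.0 * pr[_GH])
            h_inf = 0.5 * (1.0 + np.tanh((Vi - pr[_BH]) / pr[_GH]))
            kh = pr[_PHIH] * np.cosh(uh)
            h[i] = h_inf + (h[i] - h_inf) * np.exp(-dt * kh)
            m_inf = 0.5 * (1.0 + np.tanh((Vi - pr[_BM]) / pr[_GM]))
            m_inf_v = 0.5 * (1.0 + np.tanh((Vi - pr[_BMV]) / pr[_GMV]))
            na_open = (1.0 - pr[_P]) + pr[_P] * h[i]
            g_na = pr[_GNA] * na_open * m_inf + pr[_GNAV] * m_inf_v
            g_k = pr[_GK] * w[i]
            g_gaba = gg_mask[i] * gs
            g_tot = g_na + g_k + pr[_GL] + g_gaba
            rhs = (
                C / dt * Vi
                + g_na * pr[_ENA]
                + g_k * pr[_EK]
                + pr[_GL] * pr[_EL]
                + g_gaba * e_gaba
            )
            rhs += i_inj * i_mask[i]
            ncoup = 2.0
            if i == 0 or i == n - 1:
                ncoup = 1.0
            a[i] = -theta * axial
            b[i] = C / dt + theta * (g_tot + ncoup * axial)
            # explicit part of the theta-method: -(1-theta)*(G+A)V^n
            if i == 0:
                av = axial * (Vi - V[1]) if n > 1 else 0.0
            elif i == n - 1:
                av = axial * (Vi - V[n - 2])
            else:
                av = axial * (2.0 * Vi - V[i - 1] - V[i + 1])
            d[i] = rhs - (1.0 - theta) * (g_tot * Vi + av)
        # Thomas solve (sub = super = a, but a[0] unused as sub)
        cp[0] = a[0] / b[0]
        dp[0] = d[0] / b[0]
        for i in range(1, n):
            denom = b[i] - a[i] * cp[i - 1]
            cp[i] = a[i] / denom
            dp[i] = (d[i] - a[i] * dp[i - 1]) / denom
        V[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            V[i] = dp[i] - cp[i] * V[i + 1]
        ok = True
        for i in range(n):
            if not np.isfinite(V[i]):
                ok = False
        if not ok:
            status = step + 1
            break
        if t1 % stride == 0:
            j = t1 // stride
            for r in range(n_rec):
                V_rec[r, j] = V[rec_idx[r]]
    return V_rec, V, w, h, status
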