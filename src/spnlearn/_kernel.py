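"""Time-stepping kernel for the surrogate neuron.

One function advances the whole coupled system — cable voltages, spine-head
quasi-steady voltages, synaptic gating, spillover latching, VGCC gating,
calcium pools, somatic spike/reset and back-propagating depolarization — over
a stimulus window.  It is written as a plain loop nest over steps and sites so
that ``numba.njit`` can compile it; if numba is unavailable the same function
runs as pure Python (slowly, but identically).

Numerical scheme (unconditionally stable operator splitting):

1. local update — every compartment relaxes exponentially toward the reversal
   implied by its instantaneous total conductance (leak, KIR, VGCC, synaptic,
   noise) plus current sources, with the conductances frozen over the step;
2. axial update — the constant cable coupling is applied implicitly with a
   prefactorized tree (Hines) solve, exact in O(n) per step.

Spine heads are algebraic: their microsecond time constant makes them
instantaneous relative to the 0.1-0.5 ms step, so each head voltage is the
quasi-steady balance of neck, receptor and leak conductances, and the spine
couples into its shaft as a series conductance with an effective reversal.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# indices into the packed scalar parameter vector
(
    P_DT, P_ELEAK, P_EK, P_KIRVH, P_KIRK,
    P_LVAVH, P_LVAK, P_LVATAU, P_HVAVH, P_HVAK, P_HVATAU, P_ECA, P_FRACL,
    P_GMAXA, P_GMAXN, P_DECAR, P_DECAD, P_NORMA, P_DECNR, P_DECND, P_NORMN,
    P_MGC, P_MGK,
    P_SPTH, P_GMAXEX, P_DECER, P_DECED, P_NORME,
    P_DECGR, P_DECGD, P_NORMG, P_EGABA,
    P_GNE, P_GNI, P_DECNER, P_DECNED, P_NORMNE, P_DECNIR, P_DECNID, P_NORMNI, P_ENOISEI,
    P_VTH, P_VRESET, P_REFRACSTEPS, P_BAPDEC, P_DECSTEPS,
    P_SCN, P_SCL, P_SCV, P_PVMAX, P_PKM, P_TAUN, P_TAUL, P_TAUV, P_CAVBASE,
    P_INJON, P_INJOFF, P_EBAP, P_ECAN, P_KASVH, P_KASK, P_EXCAF,
) = range(62)

N_PARAMS = 62


@njit(cache=False)
def run_window(
    n_steps,
    P,
    # tree (Hines prefactorization of I + dt*C^-1*L_axial)
    parent, low, upc, dtilde,
    # per-compartment statics (uS / nF / nA)
    cm, g_leak, g_kir, g_kas, g_lva_sh, g_hva_sh, bap_inc, i_inj,
    # per-spine statics
    spine_comp, g_neck, g_lh, g_lva_h, g_hva_h, w,
    # spike-triggered calcium impulses (bAP-evoked VGCC calcium)
    bap_ca_sp, bap_ca_cm,
    # spillover units
    spine_unit, unit_comp,
    # inhibitory synapses
    inh_comp, w_inh,
    # events (sorted by step)
    ev_step, ev_type, ev_idx,
    # state (updated in place)
    V, Vh, ra, da, rn, dn, re, de, rg, dg,
    rne, dne, rni, dni,
    m_lva, m_hva, mh_lva, mh_hva,
    ca_n, ca_l, ca_v, bapI,
    unit_acc, unit_trig, unit_cnt, sp_act,
    # outputs
    peak_can, peak_cal, peak_cav, spike_steps,
    record, rec_comp, rec_spine, rec_v, rec_vh, rec_can, rec_cal, rec_cav,
):
    nc = V.shape[0]
    ns = Vh.shape[0]
    nu = unit_acc.shape[0]
    ni = w_inh.shape[0]
    ne = ev_step.shape[0]

    dt = P[P_DT]
    Gs = np.zeros(nc)
    GEs = np.zeros(nc)
    b = np.zeros(nc)

    ev_ptr = 0
    last_spike = -1000000
    nspk = 0
    nspk_dec = 0

    for step in range(n_steps):
        # --- gate decay -------------------------------------------------
        for s in range(ns):
            ra[s] *= P[P_DECAR]
            da[s] *= P[P_DECAD]
            rn[s] *= P[P_DECNR]
            dn[s] *= P[P_DECND]
        for u in range(nu):
            re[u] *= P[P_DECER]
            de[u] *= P[P_DECED]
        for j in range(ni):
            rg[j] *= P[P_DECGR]
            dg[j] *= P[P_DECGD]
        for c in range(nc):
            rne[c] *= P[P_DECNER]
            dne[c] *= P[P_DECNED]
            rni[c] *= P[P_DECNIR]
            dni[c] *= P[P_DECNID]

        # --- events -----------------------------------------------------
        while ev_ptr < ne and ev_step[ev_ptr] == step:
            k = ev_idx[ev_ptr]
            et = ev_type[ev_ptr]
            if et == 0:       # excitatory synaptic spike (saturating)
                ra[k] = 1.0
                da[k] = 1.0
                rn[k] = 1.0
                dn[k] = 1.0
                sp_act[k] = 1.0
                u = spine_unit[k]
                if u >= 0:
                    unit_acc[u] += w[k]
                    unit_cnt[u] += 1.0
                    if unit_trig[u] == 0 and unit_acc[u] >= P[P_SPTH] - 1e-12:
                        unit_trig[u] = step + 1   # latch; records trigger step + 1
                        re[u] = 1.0
                        de[u] = 1.0
            elif et == 1:     # inhibitory synaptic spike (saturating)
                rg[k] = 1.0
                dg[k] = 1.0
            elif et == 2:     # background excitatory event (non-saturating)
                rne[k] += 1.0
                dne[k] += 1.0
            else:             # background inhibitory event
                rni[k] += 1.0
                dni[k] += 1.0
            ev_ptr += 1

        for c in range(nc):
            Gs[c] = 0.0
            GEs[c] = 0.0

        # --- spines: quasi-steady head, series coupling, spine calcium --
        for s in range(ns):
            c = spine_comp[s]
            vh = Vh[s]
            B = 1.0 / (1.0 + P[P_MGC] * math.exp(-P[P_MGK] * vh))
            ga = w[s] * P[P_GMAXA] * P[P_NORMA] * (da[s] - ra[s])
            gn = w[s] * P[P_GMAXN] * P[P_NORMN] * (dn[s] - rn[s]) * B
            minf = 1.0 / (1.0 + math.exp(-(vh - P[P_LVAVH]) / P[P_LVAK]))
            mh_lva[s] += dt / P[P_LVATAU] * (minf - mh_lva[s])
            minf = 1.0 / (1.0 + math.exp(-(vh - P[P_HVAVH]) / P[P_HVAK]))
            mh_hva[s] += dt / P[P_HVATAU] * (minf - mh_hva[s])
            gca = g_lva_h[s] * mh_lva[s] + g_hva_h[s] * mh_hva[s]
            T = ga + gn + g_lh[s] + gca
            S = g_lh[s] * P[P_ELEAK] + gca * P[P_ECA]
            denom = g_neck[s] + T
            vh_new = (g_neck[s] * V[c] + S) / denom
            Vh[s] = vh_new
            Gc = g_neck[s] * T / denom
            Gs[c] += Gc
            if T > 1e-15:
                GEs[c] += Gc * (S / T)
            # calcium: NMDA pool and L-type pool (inward-positive currents).
            # The NMDA calcium component uses the calcium driving force (E_Ca
            # ~ +130 mV), not the net-current reversal at 0 mV: the net
            # current's B(V)*(V-0) product is nearly flat between -60 and
            # -20 mV and would erase the plateau/no-plateau contrast.
            i_nm = gn * (P[P_ECAN] - vh_new)
            # the extrasynaptic NMDA receptors adjacent to a co-activated
            # spine contribute to that spine's NMDA calcium pool once its
            # unit has triggered: this is what couples the pool to the
            # plateau's full duration rather than the synapse's own gating
            u = spine_unit[s]
            if u >= 0 and sp_act[s] > 0.0 and unit_trig[u] != 0:
                # this spine's own extrasynaptic share scales with its weight
                gex = (w[s] / 0.25) * P[P_GMAXEX] * P[P_NORME] * (de[u] - re[u]) * B
                i_nm += P[P_EXCAF] * gex * (P[P_ECAN] - vh_new)
            if i_nm < 0.0:
                i_nm = 0.0
            i_lt = P[P_FRACL] * g_hva_h[s] * mh_hva[s] * (P[P_ECA] - vh_new)
            if i_lt < 0.0:
                i_lt = 0.0
            can = ca_n[s] + dt * (
                P[P_SCN] * i_nm
                - P[P_PVMAX] * ca_n[s] / (ca_n[s] + P[P_PKM])
                - ca_n[s] / P[P_TAUN]
            )
            cal = ca_l[s] + dt * (
                P[P_SCL] * i_lt
                - P[P_PVMAX] * ca_l[s] / (ca_l[s] + P[P_PKM])
                - ca_l[s] / P[P_TAUL]
            )
            ca_n[s] = can if can > 0.0 else 0.0
            ca_l[s] = cal if cal > 0.0 else 0.0
            if ca_n[s] > peak_can[s]:
                peak_can[s] = ca_n[s]
            if ca_l[s] > peak_cal[s]:
                peak_cal[s] = ca_l[s]

        # --- extrasynaptic NMDA (spillover) on shafts -------------------
        # threshold-linear recruitment: glutamate escaping clearance scales
        # with the co-active weight in excess of the spillover threshold, on
        # top of one base receptor pool at the trigger point.  Potentiation
        # thus enhances spillover, and the plateau is graded steeply enough
        # in the learned weights for the soma to discriminate combinations
        for u in range(nu):
            c = unit_comp[u]
            B = 1.0 / (1.0 + P[P_MGC] * math.exp(-P[P_MGK] * V[c]))
            excess = unit_acc[u] - P[P_SPTH]
            if excess < 0.0:
                excess = 0.0
            Gs[c] += P[P_GMAXEX] * (40.0 + excess) * P[P_NORME] * (de[u] - re[u]) * B

        # --- GABA synapses ---------------------------------------------
        for j in range(ni):
            c = inh_comp[j]
            gg = w_inh[j] * P[P_NORMG] * (dg[j] - rg[j])
            Gs[c] += gg
            GEs[c] += gg * P[P_EGABA]

        # --- compartment local update + shaft calcium -------------------
        for c in range(nc):
            v = V[c]
            gk = g_kir[c] / (1.0 + math.exp((v - P[P_KIRVH]) / P[P_KIRK]))
            gk += g_kas[c] / (1.0 + math.exp(-(v - P[P_KASVH]) / P[P_KASK]))
            minf = 1.0 / (1.0 + math.exp(-(v - P[P_LVAVH]) / P[P_LVAK]))
            m_lva[c] += dt / P[P_LVATAU] * (minf - m_lva[c])
            minf = 1.0 / (1.0 + math.exp(-(v - P[P_HVAVH]) / P[P_HVAK]))
            m_hva[c] += dt / P[P_HVATAU] * (minf - m_hva[c])
            gca = g_lva_sh[c] * m_lva[c] + g_hva_sh[c] * m_hva[c]
            gne = P[P_GNE] * P[P_NORMNE] * (dne[c] - rne[c])
            gni = P[P_GNI] * P[P_NORMNI] * (dni[c] - rni[c])
            gbap = bapI[c]
            G = g_leak[c] + gk + gca + Gs[c] + gne + gni + gbap
            GE = (
                g_leak[c] * P[P_ELEAK]
                + gk * P[P_EK]
                + gca * P[P_ECA]
                + GEs[c]
                + gni * P[P_ENOISEI]
                + gbap * P[P_EBAP]
            )
            Ix = 0.0
            if step >= P[P_INJON] and step < P[P_INJOFF]:
                Ix += i_inj[c]
            kfac = dt * G / cm[c]
            if kfac > 1e-9:
                einf = (GE + Ix) / G
                b[c] = einf + (v - einf) * math.exp(-kfac)
            else:
                b[c] = v + dt * (GE + Ix - G * v) / cm[c]
            # all-VGCC shaft pool
            i_v = gca * (P[P_ECA] - v)
            if i_v < 0.0:
                i_v = 0.0
            cav = ca_v[c] + dt * (
                P[P_SCV] * i_v
                - P[P_PVMAX] * ca_v[c] / (ca_v[c] + P[P_PKM])
                - (ca_v[c] - P[P_CAVBASE]) / P[P_TAUV]
            )
            ca_v[c] = cav if cav > 0.0 else 0.0
            if ca_v[c] > peak_cav[c]:
                peak_cav[c] = ca_v[c]
            bapI[c] *= P[P_BAPDEC]

        # --- implicit axial coupling (prefactorized tree solve) ---------
        for i in range(nc - 1, 0, -1):
            b[parent[i]] -= upc[i] * b[i]
        V[0] = b[0] / dtilde[0]
        for i in range(1, nc):
            V[i] = (b[i] - low[i] * V[parent[i]]) / dtilde[i]

        # --- somatic spike ---------------------------------------------
        if (step - last_spike) < P[P_REFRACSTEPS]:
            # refractory: soma held at the reset potential (spike + AHP)
            V[0] = P[P_VRESET]
        elif V[0] >= P[P_VTH]:
            last_spike = step
            if nspk < spike_steps.shape[0]:
                spike_steps[nspk] = step
            nspk += 1
            if step < P[P_DECSTEPS]:
                nspk_dec += 1
            V[0] = P[P_VRESET]
            for c in range(nc):
                # stereotyped waveform: reset to the template, do not accumulate
                if bap_inc[c] > bapI[c]:
                    bapI[c] = bap_inc[c]
                # bAP-evoked calcium: stereotyped influx into the shaft pool
                ca_v[c] += bap_ca_cm[c]
                if ca_v[c] > peak_cav[c]:
                    peak_cav[c] = ca_v[c]
            for s in range(ns):
                # and into the spine L-type pool (distance-attenuated)
                ca_l[s] += bap_ca_sp[s]
                if ca_l[s] > peak_cal[s]:
                    peak_cal[s] = ca_l[s]

        # --- recording --------------------------------------------------
        if record == 1:
            for q in range(rec_comp.shape[0]):
                rec_v[step, q] = V[rec_comp[q]]
                rec_cav[step, q] = ca_v[rec_comp[q]]
            for q in range(rec_spine.shape[0]):
                rec_vh[step, q] = Vh[rec_spine[q]]
                rec_can[step, q] = ca_n[rec_spine[q]]
                rec_cal[step, q] = ca_l[rec_spine[q]]

    return nspk, nspk_dec


def hines_factorization(parent: np.ndarray, g_axial: np.ndarray, cm: np.ndarray, dt: float):
    """Prefactorize (I + dt * C^-1 * L_axial) for the in-kernel tree solve.

    Returns ``(low, upc, dtilde)`` where ``low[i]`` is the row-i/parent entry,
    ``upc[i]`` the elimination multiplier and ``dtilde`` the pivots.  Requires
    the tree ordering invariant parent[i] < i.
    """
    n = parent.shape[0]
    d = np.ones(n)
    low = np.zeros(n)
    up = np.zeros(n)
    for i in range(1, n):
        p = parent[i]
        g = g_axial[i]
        d[i] += dt * g / cm[i]
        d[p] += dt * g / cm[p]
        low[i] = -dt * g / cm[i]
        up[i] = -dt * g / cm[p]
    for i in range(n - 1, 0, -1):
        d[parent[i]] -= up[i] * low[i] / d[i]
    upc = np.zeros(n)
    upc[1:] = up[1:] / d[1:]
    return low, upc, d
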