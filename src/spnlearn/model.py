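"""Composition of morphology, synapses and calcium pools into a runnable cell.

:class:`SPNModel` owns the static structure (compartment tree, spine table,
synapse tables, spillover units) and a mutable :class:`ModelState`; a stimulus
window is simulated by building an event table (stimulus spikes plus
background noise) and handing everything to the compiled kernel in
:mod:`spnlearn._kernel`.

The somatic spike mechanism is threshold/reset (-60 / -68 mV) with a
refractory period; each spike injects a stereotyped back-propagating
depolarizing conductance into the dendrites whose amplitude decays
exponentially with somatic distance (length constant 120 um), so spines see
spike-driven VGCC calcium as they would from a back-propagating action
potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .calcium import CalciumScales, VgccParams
from .morphology import Morphology, PassiveParams, Spine, build_surrogate_morphology
from .synapses import (
    ExcitatorySynapse,
    InhibitorySynapse,
    NoiseProcess,
    SynapseKinetics,
    dual_exp_norm,
    generate_background_noise,
)

__all__ = ["SpikeParams", "ModelState", "WindowResult", "SPNModel", "IntegrationError"]


class IntegrationError(RuntimeError):
    pass


@dataclass
class SpikeParams:
    # threshold of the reduced somatic spike mechanism; with purely passive
    # somatic integration the in-vivo-like up-state must be able to reach it
    threshold: float = -60.0      # mV
    reset: float = -68.0          # mV
    # effective refractory of the reduced spike mechanism; keeps plateau-driven
    # firing in the tens-of-Hz range typical of SPN up-states
    refractory: float = 25.0      # ms
    # back-propagating depolarization: a weak transient conductance (the bAP's
    # calcium consequences are delivered to the pools directly; a strong
    # electrical bAP would re-ignite NMDA plateaus at high-impedance sites)
    bap_gmax: float = 2e-3        # uS at the soma end of a dendrite
    bap_reversal: float = 10.0    # mV
    bap_length_const: float = 120.0  # um
    bap_tau: float = 2.0          # ms


@dataclass
class ModelState:
    V: np.ndarray
    Vh: np.ndarray
    ra: np.ndarray
    da: np.ndarray
    rn: np.ndarray
    dn: np.ndarray
    re: np.ndarray
    de: np.ndarray
    rg: np.ndarray
    dg: np.ndarray
    rne: np.ndarray
    dne: np.ndarray
    rni: np.ndarray
    dni: np.ndarray
    m_lva: np.ndarray
    m_hva: np.ndarray
    mh_lva: np.ndarray
    mh_hva: np.ndarray
    ca_n: np.ndarray
    ca_l: np.ndarray
    ca_v: np.ndarray
    bapI: np.ndarray
    unit_acc: np.ndarray
    unit_trig: np.ndarray
    unit_cnt: np.ndarray
    sp_act: np.ndarray
    time: float = 0.0

    def copy(self) -> "ModelState":
        return ModelState(**{
            k: (v.copy() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        })


@dataclass
class WindowResult:
    n_spikes: int
    n_spikes_decision: int
    spike_times: np.ndarray          # ms
    peak_ca_nmda: np.ndarray         # per excitatory synapse, mM
    peak_ca_ltype: np.ndarray        # per excitatory synapse, mM
    peak_ca_v: np.ndarray            # per compartment, mM
    spillover_triggered: np.ndarray  # bool per unit
    traces: dict | None = None


class SPNModel:
    """Reduced SPN with spiny excitatory synapses and shaft GABA synapses."""

    def __init__(
        self,
        morphology: Morphology | None = None,
        kinetics: SynapseKinetics | None = None,
        vgcc: VgccParams | None = None,
        ca_scales: CalciumScales | None = None,
        spike: SpikeParams | None = None,
        noise: NoiseProcess | None = None,
        dt: float = 0.1,
    ):
        self.morphology = morphology or build_surrogate_morphology()
        self.kinetics = kinetics or SynapseKinetics()
        self.vgcc = vgcc or VgccParams()
        self.ca_scales = ca_scales or CalciumScales()
        self.spike = spike or SpikeParams()
        self.noise = noise or NoiseProcess()
        if not 0.01 <= dt <= 0.5:
            raise ValueError("dt must lie in [0.01, 0.5] ms")
        self.dt = dt
        self.spines: list[Spine] = []
        self.exc_synapses: list[ExcitatorySynapse] = []
        self.inh_synapses: list[InhibitorySynapse] = []
        self.spillover_mode = "clustered"
        self._finalized = False
        self.calibrated = False
        self.calibration_report: dict | None = None

    # ------------------------------------------------------------------ build

    def add_excitatory_synapse(
        self,
        compartment: int,
        w: float,
        feature: str = "unspecific",
        cluster: int | None = None,
        neck_resistance: float = 500.0,
    ) -> int:
        """Create a spine on `compartment` bearing one AMPA/NMDA synapse."""
        if self._finalized:
            raise RuntimeError("model already finalized")
        spine = Spine(shaft_compartment=compartment, neck_resistance=neck_resistance,
                      head_voltage=self.morphology.passive.e_leak)
        self.spines.append(spine)
        syn = ExcitatorySynapse(
            spine=len(self.spines) - 1, w=w, feature=feature, cluster=cluster,
            g_max_ampa=self.kinetics.g_max_ampa, g_max_nmda=self.kinetics.g_max_nmda,
        )
        self.exc_synapses.append(syn)
        return len(self.exc_synapses) - 1

    def add_inhibitory_synapse(self, compartment: int, w_inh: float,
                               feature: str = "unspecific") -> int:
        if self._finalized:
            raise RuntimeError("model already finalized")
        self.inh_synapses.append(
            InhibitorySynapse(shaft_compartment=compartment, w_inh=w_inh, feature=feature,
                              reversal=self.kinetics.e_gaba)
        )
        return len(self.inh_synapses) - 1

    def set_spillover_mode(self, mode: str):
        """'clustered': one unit per cluster id; 'branch': one unit per dendrite
        pooling every excitatory synapse on that branch (distributed setup)."""
        if mode not in ("clustered", "branch"):
            raise ValueError("spillover mode must be 'clustered' or 'branch'")
        self.spillover_mode = mode

    def finalize(self):
        """Freeze structure, build kernel arrays and the resting state."""
        m = self.morphology
        nc = m.n_comp
        ns = len(self.exc_synapses)
        ni = len(self.inh_synapses)
        kin = self.kinetics

        self.spine_comp = np.array(
            [self.spines[s.spine].shaft_compartment for s in self.exc_synapses],
            dtype=np.int64,
        ) if ns else np.empty(0, dtype=np.int64)
        self.g_neck = np.array(
            [self.spines[s.spine].neck_conductance for s in self.exc_synapses]
        ) if ns else np.empty(0)
        head_area_cm2 = np.array(
            [self.spines[s.spine].head_area * 1e-8 for s in self.exc_synapses]
        ) if ns else np.empty(0)
        self.g_lh = head_area_cm2 * m.passive.g_leak * 1e3  # uS
        self.g_lva_h = np.full(ns, self.vgcc.g_lva_spine)
        self.g_hva_h = np.full(ns, self.vgcc.g_hva_spine)
        self.w = np.array([s.w for s in self.exc_synapses]) if ns else np.empty(0)

        # spillover units
        self.spine_unit = np.full(ns, -1, dtype=np.int64)
        unit_comp = []
        if self.spillover_mode == "clustered":
            clusters = sorted({s.cluster for s in self.exc_synapses if s.cluster is not None})
            self.unit_of_cluster = {c: i for i, c in enumerate(clusters)}
            for i, s in enumerate(self.exc_synapses):
                if s.cluster is not None:
                    self.spine_unit[i] = self.unit_of_cluster[s.cluster]
            for c in clusters:
                members = [i for i, s in enumerate(self.exc_synapses) if s.cluster == c]
                comps = self.spine_comp[members]
                # unit sits at the median synapse location of the cluster
                unit_comp.append(int(np.sort(comps)[len(comps) // 2]))
        else:
            dends = sorted({int(m.dendrite[self.spine_comp[i]]) for i in range(ns)})
            self.unit_of_cluster = {d: i for i, d in enumerate(dends)}
            for i in range(ns):
                self.spine_unit[i] = self.unit_of_cluster[int(m.dendrite[self.spine_comp[i]])]
            for d in dends:
                idx = m.dendrite_compartments(d)
                unit_comp.append(int(idx[len(idx) // 2]))
        self.unit_comp = np.array(unit_comp, dtype=np.int64) if unit_comp else np.empty(0, dtype=np.int64)

        self.inh_comp = np.array(
            [s.shaft_compartment for s in self.inh_synapses], dtype=np.int64
        ) if ni else np.empty(0, dtype=np.int64)
        self.w_inh = np.array([s.w_inh for s in self.inh_synapses]) if ni else np.empty(0)

        # shaft VGCC conductances on dendrites only
        self.g_lva_sh = np.where(np.arange(nc) > 0, self.vgcc.g_lva_shaft, 0.0)
        self.g_hva_sh = np.where(np.arange(nc) > 0, self.vgcc.g_hva_shaft, 0.0)

        # bAP conductance template (uS per compartment)
        self.bap_inc = np.zeros(nc)
        dend = m.somatic_distance > 0
        self.bap_inc[dend] = self.spike.bap_gmax * np.exp(
            -m.somatic_distance[dend] / self.spike.bap_length_const
        )

        self._rebuild_step_constants()
        self._rest_state = self._make_rest_state()
        self._finalized = True
        self._relax_rest_state()

    def _rebuild_step_constants(self):
        """Everything that depends on dt (decay factors, Hines factors, P)."""
        m, kin, dt = self.morphology, self.kinetics, self.dt
        low, upc, dtilde = K.hines_factorization(m.parent, m.g_axial, m.cm, dt)
        self._low, self._upc, self._dtilde = low, upc, dtilde
        sc, vg, sp = self.ca_scales, self.vgcc, self.spike
        no = self.noise
        P = np.zeros(K.N_PARAMS)
        P[K.P_DT] = dt
        P[K.P_ELEAK] = m.passive.e_leak
        P[K.P_EK] = m.passive.e_k
        P[K.P_KIRVH] = m.passive.kir_vhalf
        P[K.P_KIRK] = m.passive.kir_slope
        P[K.P_KASVH] = m.passive.kas_vhalf
        P[K.P_KASK] = m.passive.kas_slope
        P[K.P_LVAVH] = vg.lva_vhalf
        P[K.P_LVAK] = vg.lva_slope
        P[K.P_LVATAU] = vg.lva_tau
        P[K.P_HVAVH] = vg.hva_vhalf
        P[K.P_HVAK] = vg.hva_slope
        P[K.P_HVATAU] = vg.hva_tau
        P[K.P_ECA] = vg.e_ca
        P[K.P_FRACL] = vg.l_fraction
        P[K.P_GMAXA] = kin.g_max_ampa
        P[K.P_GMAXN] = kin.g_max_nmda
        P[K.P_DECAR] = math.exp(-dt / kin.tau_ampa_rise)
        P[K.P_DECAD] = math.exp(-dt / kin.tau_ampa_decay)
        P[K.P_NORMA] = dual_exp_norm(kin.tau_ampa_rise, kin.tau_ampa_decay)
        P[K.P_DECNR] = math.exp(-dt / kin.tau_nmda_rise)
        P[K.P_DECND] = math.exp(-dt / kin.tau_nmda_decay)
        P[K.P_NORMN] = dual_exp_norm(kin.tau_nmda_rise, kin.tau_nmda_decay)
        P[K.P_MGC] = kin.mg_conc / kin.mg_k
        P[K.P_MGK] = kin.mg_slope
        P[K.P_SPTH] = 2.0
        P[K.P_GMAXEX] = kin.g_max_extrasyn_nmda
        P[K.P_DECER] = math.exp(-dt / kin.tau_extrasyn_rise)
        P[K.P_DECED] = math.exp(-dt / kin.tau_extrasyn_decay)
        P[K.P_NORME] = dual_exp_norm(kin.tau_extrasyn_rise, kin.tau_extrasyn_decay)
        P[K.P_DECGR] = math.exp(-dt / kin.tau_gaba_rise)
        P[K.P_DECGD] = math.exp(-dt / kin.tau_gaba_decay)
        P[K.P_NORMG] = dual_exp_norm(kin.tau_gaba_rise, kin.tau_gaba_decay)
        P[K.P_EGABA] = kin.e_gaba
        P[K.P_GNE] = no.exc_weight
        P[K.P_GNI] = no.inh_weight
        P[K.P_DECNER] = math.exp(-dt / no.tau_exc_rise)
        P[K.P_DECNED] = math.exp(-dt / no.tau_exc_decay)
        P[K.P_NORMNE] = dual_exp_norm(no.tau_exc_rise, no.tau_exc_decay)
        P[K.P_DECNIR] = math.exp(-dt / no.tau_inh_rise)
        P[K.P_DECNID] = math.exp(-dt / no.tau_inh_decay)
        P[K.P_NORMNI] = dual_exp_norm(no.tau_inh_rise, no.tau_inh_decay)
        P[K.P_ENOISEI] = kin.e_gaba
        P[K.P_VTH] = sp.threshold
        P[K.P_VRESET] = sp.reset
        P[K.P_REFRACSTEPS] = max(1, round(sp.refractory / dt))
        P[K.P_BAPDEC] = math.exp(-dt / sp.bap_tau)
        P[K.P_SCN] = sc.scale_nmda * sc.nmda_ca_fraction
        P[K.P_SCL] = sc.scale_ltype
        P[K.P_SCV] = sc.scale_v
        P[K.P_PVMAX] = sc.pump_vmax
        P[K.P_PKM] = sc.pump_km
        P[K.P_TAUN] = sc.tau_nmda
        P[K.P_TAUL] = sc.tau_ltype
        P[K.P_TAUV] = sc.tau_v
        P[K.P_CAVBASE] = sc.baseline_v
        P[K.P_EBAP] = sp.bap_reversal
        P[K.P_ECAN] = sc.e_ca_nmda
        P[K.P_EXCAF] = sc.extrasyn_ca_fraction
        self._P = P
        # spike-triggered calcium impulse templates (depend on the scales)
        m = self.morphology
        decay_sp = np.exp(-m.somatic_distance[self.spine_comp] / sc.bap_ca_lambda) \
            if self.spine_comp.size else np.empty(0)
        self._bap_ca_sp = sc.bap_ca_ltype * decay_sp
        decay_cm = np.where(
            m.somatic_distance > 0,
            np.exp(-m.somatic_distance / sc.bap_ca_lambda), 0.0,
        )
        self._bap_ca_cm = sc.bap_ca_v * decay_cm

    def refresh_parameters(self):
        """Re-pack kernel constants after mutating kinetics/scales in place."""
        if self._finalized:
            self._rebuild_step_constants()

    def set_dt(self, dt: float):
        if not 0.01 <= dt <= 0.5:
            raise ValueError("dt must lie in [0.01, 0.5] ms")
        self.dt = dt
        if self._finalized:
            self._rebuild_step_constants()

    def _make_rest_state(self) -> ModelState:
        m = self.morphology
        v = m.steady_state()
        nc, ns = m.n_comp, len(self.exc_synapses)
        nu, ni = self.unit_comp.shape[0], len(self.inh_synapses)
        vg = self.vgcc
        vh = v[self.spine_comp] if ns else np.empty(0)
        z = np.zeros
        st = ModelState(
            V=v.copy(), Vh=vh.copy(),
            ra=z(ns), da=z(ns), rn=z(ns), dn=z(ns),
            re=z(nu), de=z(nu), rg=z(ni), dg=z(ni),
            rne=z(nc), dne=z(nc), rni=z(nc), dni=z(nc),
            m_lva=1.0 / (1.0 + np.exp(-(v - vg.lva_vhalf) / vg.lva_slope)),
            m_hva=1.0 / (1.0 + np.exp(-(v - vg.hva_vhalf) / vg.hva_slope)),
            mh_lva=1.0 / (1.0 + np.exp(-(vh - vg.lva_vhalf) / vg.lva_slope)) if ns else z(0),
            mh_hva=1.0 / (1.0 + np.exp(-(vh - vg.hva_vhalf) / vg.hva_slope)) if ns else z(0),
            ca_n=z(ns), ca_l=z(ns),
            ca_v=np.full(nc, self.ca_scales.baseline_v),
            bapI=z(nc),
            unit_acc=z(nu), unit_trig=z(nu), unit_cnt=z(nu), sp_act=z(ns),
        )
        return st

    def _relax_rest_state(self, duration: float = 2000.0):
        """Relax the analytic passive rest to the kernel's exact fixed point.

        The KIR chord solution ignores the (small) VGCC window conductance
        and the calcium pools' resting influx; 2 s of quiet integration (over
        20 time constants of the slowest state) lands on the true baseline.
        """
        st = self._rest_state
        self.run_window(duration, state=st)
        st.time = 0.0
        st.bapI[:] = 0.0

    # ------------------------------------------------------------------ run

    def rest_state(self) -> ModelState:
        return self._rest_state.copy()

    def set_weights(self, w: np.ndarray):
        self.w[:] = np.clip(w, 0.0, None)

    def set_inhibitory_weights(self, w_inh: np.ndarray):
        self.w_inh[:] = np.clip(w_inh, 0.0, None)

    def make_event_arrays(
        self,
        n_steps: int,
        exc_events: tuple[np.ndarray, np.ndarray] | None = None,
        inh_events: tuple[np.ndarray, np.ndarray] | None = None,
        noise_events: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    ):
        """Merge stimulus and noise events into step-sorted kernel arrays."""
        steps, types, idxs = [], [], []
        if exc_events is not None and len(exc_events[0]):
            t, i = exc_events
            steps.append(np.asarray(t) / self.dt)
            types.append(np.zeros(len(t)))
            idxs.append(np.asarray(i))
        if inh_events is not None and len(inh_events[0]):
            t, i = inh_events
            steps.append(np.asarray(t) / self.dt)
            types.append(np.ones(len(t)))
            idxs.append(np.asarray(i))
        if noise_events is not None and len(noise_events[0]):
            t, c, kind = noise_events
            steps.append(np.asarray(t) / self.dt)
            types.append(2.0 + np.asarray(kind))
            idxs.append(np.asarray(c))
        if not steps:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy(), e.copy()
        st = np.floor(np.concatenate(steps)).astype(np.int64)
        st = np.clip(st, 0, n_steps - 1)
        ty = np.concatenate(types).astype(np.int64)
        ix = np.concatenate(idxs).astype(np.int64)
        order = np.argsort(st, kind="stable")
        return st[order], ty[order], ix[order]

    def run_window(
        self,
        duration: float,
        state: ModelState | None = None,
        exc_events: tuple[np.ndarray, np.ndarray] | None = None,
        inh_events: tuple[np.ndarray, np.ndarray] | None = None,
        noise_rng: np.random.Generator | None = None,
        decision_window: float | None = None,
        i_inj: np.ndarray | None = None,
        inj_window: tuple[float, float] | None = None,
        record: bool = False,
        rec_comps: np.ndarray | None = None,
        rec_spines: np.ndarray | None = None,
    ) -> WindowResult:
        """Simulate `duration` ms from `state` (resting state by default).

        ``noise_rng`` enables background noise; the state is modified in place
        and peak calcium trackers start fresh at the window onset.
        """
        if not self._finalized:
            raise RuntimeError("finalize() the model before running")
        st = state if state is not None else self.rest_state()
        n_steps = int(round(duration / self.dt))
        noise_events = None
        if noise_rng is not None and (self.noise.exc_rate > 0 or self.noise.inh_rate > 0):
            noise_events = generate_background_noise(
                self.noise, duration, self.morphology.n_comp, rng=noise_rng
            )
        ev_step, ev_type, ev_idx = self.make_event_arrays(
            n_steps, exc_events, inh_events, noise_events
        )
        nc = self.morphology.n_comp
        ns = len(self.exc_synapses)
        inj = np.zeros(nc) if i_inj is None else np.asarray(i_inj, dtype=float)
        P = self._P.copy()
        if inj_window is not None:
            P[K.P_INJON] = inj_window[0] / self.dt
            P[K.P_INJOFF] = inj_window[1] / self.dt
        elif i_inj is not None:
            P[K.P_INJON] = 0.0
            P[K.P_INJOFF] = float(n_steps)
        P[K.P_DECSTEPS] = (
            (decision_window / self.dt) if decision_window is not None else float(n_steps)
        )
        peak_can = np.zeros(ns)
        peak_cal = np.zeros(ns)
        peak_cav = np.zeros(nc)
        spike_steps = np.full(512, -1, dtype=np.int64)
        st.unit_acc[:] = 0.0
        st.unit_trig[:] = 0.0
        st.unit_cnt[:] = 0.0
        st.sp_act[:] = 0.0
        rc = np.asarray(rec_comps if rec_comps is not None else [0], dtype=np.int64)
        rs = np.asarray(
            rec_spines if rec_spines is not None else np.arange(min(ns, 1)), dtype=np.int64
        )
        if record:
            rec_v = np.zeros((n_steps, rc.size))
            rec_cav = np.zeros((n_steps, rc.size))
            rec_vh = np.zeros((n_steps, rs.size))
            rec_can = np.zeros((n_steps, rs.size))
            rec_cal = np.zeros((n_steps, rs.size))
        else:
            rec_v = rec_cav = np.zeros((0, rc.size))
            rec_vh = rec_can = rec_cal = np.zeros((0, rs.size))
        nspk, nspk_dec = K.run_window(
            n_steps, P,
            self.morphology.parent, self._low, self._upc, self._dtilde,
            self.morphology.cm, self.morphology.g_leak, self.morphology.g_kir,
            self.morphology.g_kas, self.g_lva_sh, self.g_hva_sh, self.bap_inc, inj,
            self.spine_comp, self.g_neck, self.g_lh, self.g_lva_h, self.g_hva_h, self.w,
            self._bap_ca_sp, self._bap_ca_cm,
            self.spine_unit, self.unit_comp,
            self.inh_comp, self.w_inh,
            ev_step, ev_type, ev_idx,
            st.V, st.Vh, st.ra, st.da, st.rn, st.dn, st.re, st.de, st.rg, st.dg,
            st.rne, st.dne, st.rni, st.dni,
            st.m_lva, st.m_hva, st.mh_lva, st.mh_hva,
            st.ca_n, st.ca_l, st.ca_v, st.bapI,
            st.unit_acc, st.unit_trig, st.unit_cnt, st.sp_act,
            peak_can, peak_cal, peak_cav, spike_steps,
            1 if record else 0, rc, rs, rec_v, rec_vh, rec_can, rec_cal, rec_cav,
        )
        if not np.all(np.isfinite(st.V)):
            bad = int(np.nonzero(~np.isfinite(st.V))[0][0])
            raise IntegrationError(f"non-finite voltage in compartment {bad}")
        st.time += duration
        times = spike_steps[: min(nspk, spike_steps.size)]
        traces = None
        if record:
            traces = {
                "t": np.arange(n_steps) * self.dt,
                "v_comp": rec_v, "ca_v": rec_cav, "rec_comps": rc,
                "v_spine": rec_vh, "ca_nmda": rec_can, "ca_ltype": rec_cal,
                "rec_spines": rs,
            }
        return WindowResult(
            n_spikes=nspk,
            n_spikes_decision=nspk_dec,
            spike_times=times[times >= 0] * self.dt,
            peak_ca_nmda=peak_can,
            peak_ca_ltype=peak_cal,
            peak_ca_v=peak_cav,
            spillover_triggered=st.unit_trig > 0,
            traces=traces,
        )

    def step_membrane(self, state: ModelState, synaptic_currents: np.ndarray | None = None,
                      dt: float | None = None) -> ModelState:
        """Advance the membrane one step with optional per-compartment currents (nA)."""
        if dt is not None and dt != self.dt:
            self.set_dt(dt)
        self.run_window(self.dt, state=state, i_inj=synaptic_currents)
        return state

    # ------------------------------------------------------ calibration probe

    def probe_cluster_window(
        self,
        n_active: int,
        weight: float,
        force_spike: bool = False,
        duration: float = 350.0,
        unit: int | None = None,
        noise_seed: int = 12345,
        full_stimulus: bool = False,
    ) -> dict:
        """Deterministic activation of `n_active` synapses of one spillover
        unit at a common weight; used by the calcium calibration.

        The probe reproduces training conditions: one spike per synapse spread
        over a 20 ms stimulus window and background noise from a fixed seed;
        ``force_spike`` adds a moderate somatic current so the window contains
        a somatic spike (and hence bAP-driven calcium).  Returns peak calcium
        measures averaged over the activated spines and the shaft [Ca]_v peak
        at the unit compartment.
        """
        if self.unit_comp.size == 0:
            raise RuntimeError("model has no spillover units to probe")
        if unit is None:
            sizes = [int(np.sum(self.spine_unit == u)) for u in range(self.unit_comp.size)]
            unit = int(np.argmax(sizes))
        members = np.nonzero(self.spine_unit == unit)[0]
        if members.size < n_active:
            raise ValueError(f"unit {unit} has only {members.size} synapses")
        active = members[:n_active]
        w_saved = self.w.copy()
        try:
            self.w[active] = weight
            ev_t = np.linspace(2.0, 20.0, active.size)
            ev_i = active
            if full_stimulus:
                # reproduce a full training stimulus: the unit's synapses plus
                # the feature-unspecific population over its 50 ms window
                unspec = np.array(
                    [i for i, s in enumerate(self.exc_synapses)
                     if s.feature == "unspecific"], dtype=np.int64,
                )
                if unspec.size:
                    rng_u = np.random.default_rng(noise_seed + 1)
                    ev_t = np.concatenate([ev_t, rng_u.uniform(0.0, 50.0, unspec.size)])
                    ev_i = np.concatenate([ev_i, unspec])
            ev = (ev_t, ev_i)
            inj = None
            window = None
            if force_spike:
                inj = np.zeros(self.morphology.n_comp)
                inj[0] = 0.8
                window = (40.0, 55.0)
            res = self.run_window(
                duration, exc_events=ev, i_inj=inj, inj_window=window,
                noise_rng=np.random.default_rng(noise_seed),
            )
        finally:
            self.w[:] = w_saved
        return {
            "spillover": bool(res.spillover_triggered[unit]),
            "peak_ca_nmda": float(np.mean(res.peak_ca_nmda[active])),
            "peak_ca_ltype": float(np.mean(res.peak_ca_ltype[active])),
            "peak_ca_v": float(res.peak_ca_v[self.unit_comp[unit]]),
            "n_spikes": res.n_spikes,
        }
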