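"""Reduced compartmental surrogate of a striatal projection neuron (SPN).

The electrical substrate is deliberately minimal: a soma plus unbranched,
tapering dendrites built from short cable segments, with a passive leak and an
inward-rectifier (KIR)-like potassium conductance in every compartment.  KIR
dominates the resting conductance of SPNs and is responsible for both their
very hyperpolarized resting potential (about -85 mV) and the increase in input
resistance as the cell depolarizes, which is the substrate the dendritic
nonlinearities ride on.  Fast spike-generating currents are replaced by a
somatic threshold/reset mechanism (see :mod:`spnlearn.model`), because the
plasticity rules consume only local voltage, local calcium and the binary
somatic spike decision.

Units used throughout the package: mV, ms, nA, uS (microsiemens), nF, mM, um.
With these, uS * mV = nA and nF / uS = ms, so no conversion constants appear
in the integrator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PassiveParams",
    "Compartment",
    "Spine",
    "Morphology",
    "build_surrogate_morphology",
    "input_impedance",
    "detect_somatic_spikes",
]

# Spatial resolution guard: segments longer than this are electrically too
# coarse for the plateau-potential length scales simulated here.
MAX_SEGMENT_LENGTH_UM = 40.0


@dataclass
class PassiveParams:
    """Passive and KIR membrane parameters of the surrogate.

    The resting potential is an emergent property of ``g_leak``/``e_leak``
    against the KIR conductance (reversal ``e_k``); defaults put it near
    -84 mV, inside the -90..-80 mV band typical of SPNs in vitro.
    """

    ra: float = 150.0            # axial resistivity, ohm*cm
    cm: float = 1.0              # specific capacitance, uF/cm^2
    g_leak: float = 0.10         # leak density, mS/cm^2
    e_leak: float = -85.0        # mV
    g_kir: float = 0.15          # KIR density, mS/cm^2
    e_k: float = -90.0           # mV
    kir_vhalf: float = -82.0     # KIR activation midpoint, mV (closes on depol.)
    kir_slope: float = 13.0      # mV
    # slow A-type (KAs-like) potassium: opens on depolarization and stabilizes
    # the global up-state where KIR has closed; per-compartment it is far too
    # small to oppose a clustered NMDA plateau
    g_kas: float = 0.2           # mS/cm^2
    kas_vhalf: float = -55.0     # mV
    kas_slope: float = 8.0       # mV

    def kir_activation(self, v):
        """KIR open fraction; a decreasing sigmoid of voltage."""
        return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - self.kir_vhalf) / self.kir_slope))

    def kas_activation(self, v):
        """KAs open fraction; an increasing sigmoid of voltage."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.kas_vhalf) / self.kas_slope))


@dataclass
class Compartment:
    id: int
    parent: int | None           # None only for the soma
    length: float                # um
    diameter: float              # um
    somatic_distance: float      # um, path distance of the midpoint to soma
    membrane_capacitance: float  # uF/cm^2
    leak_conductance: float      # mS/cm^2
    leak_reversal: float         # mV
    kir_conductance: float       # mS/cm^2
    dendrite: int = -1           # index of the dendrite (branch), -1 for soma

    @property
    def area_cm2(self) -> float:
        # open cylinder; the soma uses its own L = diam convention
        return math.pi * self.diameter * 1e-4 * self.length * 1e-4

    @property
    def cross_section_cm2(self) -> float:
        return math.pi * (self.diameter * 1e-4) ** 2 / 4.0


@dataclass
class Spine:
    """Two-compartment spine reduced to a neck resistance + head node.

    The head is treated as being in instantaneous equilibrium with the shaft
    through the neck (its capacitance, ~0.01 pF, gives a microsecond time
    constant), so ``head_voltage`` is algebraic, not integrated.
    """

    shaft_compartment: int
    neck_resistance: float = 500.0   # MOhm
    head_area: float = 1.0           # um^2
    head_voltage: float = -85.0      # mV

    def __post_init__(self):
        if self.neck_resistance <= 0:
            raise ValueError("spine neck resistance must be positive")

    @property
    def neck_conductance(self) -> float:
        """uS (1/MOhm = uS)."""
        return 1.0 / self.neck_resistance


class Morphology:
    """A tree of compartments with precomputed cable quantities."""

    def __init__(self, compartments: list[Compartment], passive: PassiveParams):
        roots = [c for c in compartments if c.parent is None]
        if len(roots) != 1 or roots[0].id != 0:
            raise ValueError("exactly one root (soma, id 0) is required")
        self.compartments = compartments
        self.passive = passive
        n = len(compartments)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.length = np.empty(n)
        self.diameter = np.empty(n)
        self.somatic_distance = np.empty(n)
        self.dendrite = np.full(n, -1, dtype=np.int64)
        for c in compartments:
            if c.id < 0 or c.id >= n:
                raise ValueError("compartment ids must be 0..n-1")
            self.parent[c.id] = -1 if c.parent is None else c.parent
            self.length[c.id] = c.length
            self.diameter[c.id] = c.diameter
            self.somatic_distance[c.id] = c.somatic_distance
            self.dendrite[c.id] = c.dendrite
        if np.any(self.length <= 0) or np.any(self.diameter <= 0):
            raise ValueError("compartment geometry must be positive")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children (tree ordering)")
        self._check_tree()
        self.area = np.array([c.area_cm2 for c in compartments])          # cm^2
        self.cm = self.area * np.array([c.membrane_capacitance for c in compartments]) * 1e3   # nF
        self.g_leak = self.area * np.array([c.leak_conductance for c in compartments]) * 1e3   # uS
        self.g_kir = self.area * np.array([c.kir_conductance for c in compartments]) * 1e3     # uS
        self.g_kas = self.area * passive.g_kas * 1e3                                           # uS
        self.e_leak = np.array([c.leak_reversal for c in compartments])
        self.g_axial = self._axial_conductances()   # uS, per non-root compartment

    # -- construction helpers -------------------------------------------------

    def _check_tree(self):
        # parents strictly precede children, so connectivity to the root is
        # guaranteed iff every non-root parent is valid
        if np.any(self.parent[1:] < 0):
            raise ValueError("only the soma may lack a parent")

    def _axial_conductances(self) -> np.ndarray:
        ra = self.passive.ra
        half_r = np.array(
            [ra * (c.length * 1e-4 / 2.0) / c.cross_section_cm2 for c in self.compartments]
        )  # ohm
        g = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            r = half_r[i] + half_r[self.parent[i]]
            g[i] = 1e6 / r  # uS
        return g

    # -- basic queries --------------------------------------------------------

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    def children(self, i: int) -> np.ndarray:
        return np.nonzero(self.parent == i)[0]

    def dendrite_compartments(self, d: int) -> np.ndarray:
        return np.nonzero(self.dendrite == d)[0]

    def compartment_at(self, dendrite: int, distance_um: float) -> int:
        """Compartment on `dendrite` whose midpoint is closest to the distance."""
        idx = self.dendrite_compartments(dendrite)
        if idx.size == 0:
            raise KeyError(f"no dendrite {dendrite}")
        return int(idx[np.argmin(np.abs(self.somatic_distance[idx] - distance_um))])

    # -- linear algebra -------------------------------------------------------

    def laplacian(self) -> np.ndarray:
        """Axial conductance Laplacian (uS); symmetric, zero row sums."""
        n = self.n_comp
        L = np.zeros((n, n))
        for i in range(1, n):
            p = self.parent[i]
            g = self.g_axial[i]
            L[i, i] += g
            L[p, p] += g
            L[i, p] -= g
            L[p, i] -= g
        return L

    def steady_state(
        self,
        i_inj: np.ndarray | None = None,
        kir: bool = True,
        tol: float = 1e-12,
        max_iter: int = 2000,
        damping: float = 0.5,
    ) -> np.ndarray:
        """Steady-state voltages for constant injected currents (nA).

        Solves the nonlinear (KIR chord conductance) system by fixed-point
        iteration of linear solves; with ``kir=False`` this is the exact
        solution of the discrete passive cable and serves as the analytic
        reference for the time-stepping integrator.
        """
        n = self.n_comp
        inj = np.zeros(n) if i_inj is None else np.asarray(i_inj, dtype=float)
        L = self.laplacian()
        v = np.full(n, self.passive.e_leak)
        for _ in range(max_iter):
            if kir:
                gk = (self.g_kir * self.passive.kir_activation(v)
                      + self.g_kas * self.passive.kas_activation(v))
            else:
                gk = 0.0
            G = L + np.diag(self.g_leak + gk)
            rhs = self.g_leak * self.e_leak + gk * self.passive.e_k + inj
            v_new = np.linalg.solve(G, rhs)
            if np.max(np.abs(v_new - v)) < tol:
                return v_new
            # damped update: the KIR chord iteration can oscillate when the
            # rectifier is strongly engaged
            v = damping * v_new + (1.0 - damping) * v
        raise RuntimeError("steady-state iteration did not converge")

    def resting_potential(self) -> np.ndarray:
        return self.steady_state()

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "units": {"length": "um", "diameter": "um", "capacitance": "uF/cm^2",
                      "conductance": "mS/cm^2", "voltage": "mV", "ra": "ohm*cm"},
            "passive": asdict(self.passive),
            "compartments": [asdict(c) for c in self.compartments],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Morphology":
        payload = json.loads(text)
        passive = PassiveParams(**payload["passive"])
        comps = [Compartment(**c) for c in payload["compartments"]]
        return cls(comps, passive)


def build_surrogate_morphology(
    n_dendrites: int = 6,
    dendrite_length: float = 200.0,
    segments_per_dendrite: int = 10,
    taper: float = 0.8,
    proximal_diameter: float = 0.8,
    soma_diameter: float = 15.0,
    passive: PassiveParams | None = None,
) -> Morphology:
    """Soma plus ``n_dendrites`` unbranched tapering dendrites.

    ``taper`` is the distal/proximal diameter ratio; the diameter decreases
    linearly along each dendrite, which satisfies the non-increasing-diameter
    invariant and gives distal segments the high local input impedance needed
    for location-dependent plateau efficacy.
    """
    if n_dendrites < 2:
        raise ValueError("need at least two dendrites")
    if dendrite_length < 200.0:
        raise ValueError("dendrites must be at least 200 um to span the placement range")
    if segments_per_dendrite < 4:
        raise ValueError("need at least four segments per dendrite")
    if taper <= 0 or taper > 1 or proximal_diameter <= 0 or soma_diameter <= 0:
        raise ValueError("geometry parameters must be positive (taper in (0, 1])")
    seg_len = dendrite_length / segments_per_dendrite
    if seg_len > MAX_SEGMENT_LENGTH_UM:
        raise ValueError(
            f"segment length {seg_len:.1f} um exceeds the {MAX_SEGMENT_LENGTH_UM} um resolution guard"
        )
    passive = passive or PassiveParams()
    mk = dict(
        membrane_capacitance=passive.cm,
        leak_conductance=passive.g_leak,
        leak_reversal=passive.e_leak,
        kir_conductance=passive.g_kir,
    )
    comps = [Compartment(id=0, parent=None, length=soma_diameter,
                         diameter=soma_diameter, somatic_distance=0.0, dendrite=-1, **mk)]
    next_id = 1
    for d in range(n_dendrites):
        parent = 0
        for k in range(segments_per_dendrite):
            frac = (k + 0.5) / segments_per_dendrite
            diam = proximal_diameter * (1.0 + (taper - 1.0) * frac)
            comps.append(
                Compartment(
                    id=next_id, parent=parent, length=seg_len, diameter=diam,
                    somatic_distance=seg_len * (k + 0.5), dendrite=d, **mk,
                )
            )
            parent = next_id
            next_id += 1
    return Morphology(comps, passive)


def input_impedance(morphology: Morphology, site: int, i_test: float = 0.01) -> float:
    """Steady-state local input impedance (MOhm) at `site` around rest.

    Computed as the local voltage deflection per unit current for a small test
    current, with the KIR chord conductance re-solved at the displaced state.
    """
    if site < 0 or site >= morphology.n_comp:
        raise KeyError(f"unknown compartment id {site}")
    v0 = morphology.steady_state()
    inj = np.zeros(morphology.n_comp)
    inj[site] = i_test
    v1 = morphology.steady_state(i_inj=inj)
    return float((v1[site] - v0[site]) / i_test)  # mV / nA = MOhm


def detect_somatic_spikes(
    voltage_trace: np.ndarray,
    dt: float,
    threshold: float = -40.0,
    refractory: float = 5.0,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by >= refractory."""
    v = np.asarray(voltage_trace, dtype=float)
    if v.size == 0:
        return np.empty(0)
    above = v >= threshold
    crossings = np.nonzero(above & ~np.concatenate(([False], above[:-1])))[0]
    spikes = []
    last = -np.inf
    for idx in crossings:
        t = idx * dt
        if t - last >= refractory:
            spikes.append(t)
            last = t
    return np.asarray(spikes)
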