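"""Compartment trees, mechanisms and the Ca-AdEx genome.

The Ca-AdEx neuron is a two-compartment spiking model: a somatic/basal
compartment carrying an adaptive exponential integrate-and-fire (AdEx) spike
mechanism, and a distal apical compartment carrying a high-voltage-activated
Ca2+ channel, a Ca2+-activated K+ channel and a calcium pool (the "calcium
hot zone", Ca-HZ).  The two are coupled by a single conductance ``g_C``.

More generally, any tree of passive compartments with per-compartment
channels and receptors can be built (:func:`build_tree`); the membrane
equation in every compartment ``i`` is

    C_i dV_i/dt = g_L_i (E_L_i - V_i) + sum_channels I + sum_receptors I
                  + sum_{j in neighbours} g_C_ij (V_j - V_i)

with symmetric coupling (one conductance per edge).  Units are fixed
throughout the package: pF, nS, mV, ms, pA, mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ConfigurationError",
    "StructureError",
    "ValidationError",
    "AdExMechanism",
    "CaHotzoneMechanism",
    "Compartment",
    "CompartmentTree",
    "Genome",
    "GENOME_PARAMETERS",
    "DEFAULT_BOUNDS",
    "build_two_compartment",
    "build_tree",
    "validate_genome",
]


class ConfigurationError(ValueError):
    """A parameter set is incomplete or internally inconsistent."""


class StructureError(ValueError):
    """A compartment layout is not a valid tree."""


class ValidationError(ValueError):
    """A value violates its declared bounds."""


@dataclass
class AdExMechanism:
    """Adaptive exponential integrate-and-fire spike mechanism.

    Attached to the somatic compartment.  Contributes the exponential
    spike-initiation current ``g_L * Delta_T * exp((V - V_th_s)/Delta_T)``
    and the adaptation current ``-g_w * w``; the adaptation variable obeys
    ``tau_w dw/dt = a (V - E_L) - w`` and jumps by ``b`` at each spike.
    A spike is detected when ``V >= V_th``; the membrane is clamped at
    ``V_reset`` for ``t_ref`` afterwards, and a back-propagating action
    potential delivers the charge ``w_BAP`` (pA*ms) into the distal
    compartment ``d_BAP`` ms after each spike.
    """

    Delta_T: float          # slope factor, mV
    V_th_s: float           # exponential threshold, mV
    V_th: float             # spike-detection threshold, mV
    V_reset: float          # reset potential, mV
    t_ref: float            # refractory period, ms
    a: float                # subthreshold adaptation, nS
    b: float                # spike-triggered adaptation increment, pA
    tau_w: float            # adaptation time constant, ms
    g_w: float = 1.0        # adaptation coupling factor (dimensionless)
    w_BAP: float = 0.0      # BAP charge, pA*ms
    d_BAP: float = 0.0      # BAP delay, ms

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.Delta_T) > 0):
            raise ConfigurationError("Delta_T must be > 0")
        if not np.all(np.asarray(self.t_ref) >= 0):
            raise ConfigurationError("t_ref must be >= 0")
        if not np.all(np.asarray(self.tau_w) > 0):
            raise ConfigurationError("tau_w must be > 0")


@dataclass
class CaHotzoneMechanism:
    """High-voltage-activated Ca2+ channel, Ca-activated K+ channel, Ca pool.

    The calcium current is ``I_Ca = g_Ca * m * h * (E_Ca - V)`` with
    sigmoidal steady states ``m_inf = 1/(1+exp(m_slope (V - m_half)))`` (a
    negative slope gives activation increasing with V) and first-order
    kinetics.  The repolarizing potassium current is
    ``I_KCa = g_K * m * (E_K - V)`` with a calcium-dependent activation
    ``m_inf = 1/(1 + (Ca_th/[Ca])**const_KCa)``.  The pool obeys
    ``d[Ca]/dt = phi_Ca * I_Ca - ([Ca] - Ca_0)/tau_Ca``.
    """

    g_Ca: float             # maximal Ca conductance, nS
    E_Ca: float             # Ca reversal, mV
    m_slope: float          # 1/mV (negative => activation)
    m_half: float           # mV
    tau_m_Ca: float         # ms
    h_slope: float          # 1/mV (positive => inactivation)
    h_half: float           # mV
    tau_h_Ca: float         # ms
    g_K: float              # maximal K_Ca conductance, nS
    E_K: float              # K reversal, mV
    tau_m_KCa: float        # ms
    Ca_th: float            # half-activation Ca concentration, mM
    const_KCa: float        # Hill-like exponent
    phi_Ca: float           # current-to-concentration scale, mM/(pA*ms)
    Ca_0: float             # baseline concentration, mM
    tau_Ca: float           # extrusion time constant, ms

    def __post_init__(self) -> None:
        for name in ("tau_m_Ca", "tau_h_Ca", "tau_m_KCa", "tau_Ca"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ConfigurationError(f"{name} must be > 0")
        if not np.all(np.asarray(self.Ca_th) > 0):
            raise ConfigurationError("Ca_th must be > 0")
        if not np.all(np.asarray(self.Ca_0) >= 0):
            raise ConfigurationError("Ca_0 must be >= 0")


@dataclass
class Compartment:
    """One node of a compartment tree.

    ``parent`` is the index of the parent compartment or ``None`` for the
    root (soma).  ``g_C`` is the coupling conductance to the parent; it is
    stored on the child, used symmetrically on both sides of the edge.
    """

    id: int
    parent: Optional[int]
    C_m: float              # pF
    g_L: float              # nS
    E_L: float              # mV
    g_C: float = 0.0        # nS, to parent (ignored at the root)
    channels: list = field(default_factory=list)
    receptors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.C_m) > 0):
            raise ConfigurationError(f"compartment {self.id}: C_m must be > 0")
        if not np.all(np.asarray(self.g_L) >= 0):
            raise ConfigurationError(f"compartment {self.id}: g_L must be >= 0")
        if not np.all(np.asarray(self.g_C) >= 0):
            raise ConfigurationError(f"compartment {self.id}: g_C must be >= 0")


@dataclass
class CompartmentTree:
    """Validated tree of compartments in Hines order (children after parents)."""

    compartments: list

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def soma(self) -> Compartment:
        return self.compartments[0]

    def adex(self) -> Optional[AdExMechanism]:
        """The AdEx mechanism on the soma, if present."""
        for ch in self.soma.channels:
            if isinstance(ch, AdExMechanism):
                return ch
        return None

    def hotzone_index(self) -> Optional[int]:
        """Index of the first compartment carrying a Ca hot zone."""
        for comp in self.compartments:
            for ch in comp.channels:
                if isinstance(ch, CaHotzoneMechanism):
                    return comp.id
        return None


def build_tree(compartments: list) -> CompartmentTree:
    """Validate a list of :class:`Compartment` and assemble a tree.

    Parents must precede children (Hines ordering), there must be exactly
    one root, and the parent links must form a connected acyclic graph.
    """
    if not compartments:
        raise StructureError("empty compartment list")
    roots = [c for c in compartments if c.parent is None]
    if len(roots) != 1:
        raise StructureError(f"expected exactly one root, found {len(roots)}")
    if roots[0].id != compartments[0].id:
        raise StructureError("the root must be the first compartment (soma)")
    ids = [c.id for c in compartments]
    if ids != list(range(len(compartments))):
        raise StructureError("compartment ids must be 0..n-1 in order")
    for c in compartments[1:]:
        if c.parent is None:
            continue
        if c.parent == c.id:
            raise StructureError(f"compartment {c.id} is its own parent")
        if not (0 <= c.parent < c.id):
            raise StructureError(
                f"compartment {c.id}: parent {c.parent} must be an earlier index"
            )
    # parents-precede-children on 0..n-1 implies connected + acyclic:
    # n-1 edges, each node reaches 0 by strictly decreasing parent hops.
    return CompartmentTree(compartments=list(compartments))


#: Names, units and roles of every Ca-AdEx genome parameter.
GENOME_PARAMETERS: tuple = (
    # somatic compartment
    "C_m_s", "g_L_s", "E_L_s", "g_C",
    # AdEx mechanism
    "Delta_T", "V_th_s", "V_th", "V_reset", "t_ref",
    "a", "b", "tau_w", "g_w", "w_BAP", "d_BAP",
    # distal compartment (passive part)
    "C_m_d", "g_L_d", "E_L_d",
    # Ca channel
    "g_Ca", "E_Ca", "m_slope", "m_half", "tau_m_Ca",
    "h_slope", "h_half", "tau_h_Ca",
    # K_Ca channel
    "g_K", "E_K", "tau_m_KCa", "Ca_th", "const_KCa",
    # calcium pool
    "phi_Ca", "Ca_0", "tau_Ca",
)

#: Biologically plausible closed-interval bounds for each parameter.
DEFAULT_BOUNDS: dict = {
    "C_m_s": (50.0, 600.0),
    "g_L_s": (2.0, 60.0),
    "E_L_s": (-90.0, -55.0),
    "g_C": (0.0, 60.0),
    "Delta_T": (0.5, 6.0),
    "V_th_s": (-60.0, -40.0),
    "V_th": (-45.0, 10.0),
    "V_reset": (-90.0, -45.0),
    "t_ref": (0.0, 6.0),
    "a": (0.0, 40.0),
    "b": (0.0, 300.0),
    "tau_w": (10.0, 600.0),
    "g_w": (0.5, 2.0),
    "w_BAP": (0.0, 12000.0),
    "d_BAP": (0.0, 5.0),
    "C_m_d": (20.0, 600.0),
    "g_L_d": (1.0, 40.0),
    "E_L_d": (-90.0, -55.0),
    "g_Ca": (0.0, 40.0),
    "E_Ca": (20.0, 140.0),
    "m_slope": (-2.0, -0.05),
    "m_half": (-45.0, -5.0),
    "tau_m_Ca": (0.5, 40.0),
    "h_slope": (0.05, 2.0),
    "h_half": (-60.0, -10.0),
    "tau_h_Ca": (5.0, 500.0),
    "g_K": (0.0, 60.0),
    "E_K": (-100.0, -70.0),
    "tau_m_KCa": (0.5, 60.0),
    "Ca_th": (1e-5, 1e-2),
    "const_KCa": (1.0, 8.0),
    "phi_Ca": (1e-9, 1e-5),
    "Ca_0": (0.0, 1e-3),
    "tau_Ca": (10.0, 500.0),
}


@dataclass
class Genome:
    """The full Ca-AdEx parameter vector searched by the evolutionary fit.

    ``values`` maps every name in :data:`GENOME_PARAMETERS` to a float;
    ``bounds`` maps each name to a closed interval ``(low, high)``.
    """

    values: dict
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ConfigurationError(f"genome is missing parameter '{name}'") from None

    def replace(self, **updates: float) -> "Genome":
        """Return a copy with the given parameters replaced."""
        unknown = set(updates) - set(GENOME_PARAMETERS)
        if unknown:
            raise ConfigurationError(f"unknown genome parameter(s): {sorted(unknown)}")
        vals = dict(self.values)
        vals.update(updates)
        return Genome(values=vals, bounds=dict(self.bounds))

    def check_complete(self) -> None:
        missing = [p for p in GENOME_PARAMETERS if p not in self.values]
        if missing:
            raise ConfigurationError(f"genome is missing parameter '{missing[0]}'")


def validate_genome(genome: Genome, bounds: Optional[dict] = None) -> list:
    """Report bound violations as a list of ``(name, value, low, high)``.

    Bounds are closed intervals; a value exactly at a bound is valid.  An
    empty report means the genome is valid.  Missing parameters are
    reported with value ``None``.
    """
    bounds = bounds if bounds is not None else genome.bounds
    report = []
    for name in GENOME_PARAMETERS:
        if name not in genome.values:
            report.append((name, None, *bounds.get(name, (None, None))))
            continue
        if name not in bounds:
            continue
        lo, hi = bounds[name]
        v = genome.values[name]
        if not (lo <= v <= hi):
            report.append((name, v, lo, hi))
    return report


def build_two_compartment(genome: Genome) -> CompartmentTree:
    """Build the canonical two-compartment Ca-AdEx tree from a genome.

    Compartment 0 is the soma (AdEx mechanism), compartment 1 the distal
    apical compartment (Ca hot zone), coupled by ``g_C``.  Raises
    :class:`ConfigurationError` for a missing parameter and
    :class:`ValidationError` if any value is outside its bounds.
    """
    genome.check_complete()
    violations = validate_genome(genome)
    if violations:
        name, v, lo, hi = violations[0]
        raise ValidationError(f"parameter '{name}' = {v} outside bounds [{lo}, {hi}]")
    g = genome
    adex = AdExMechanism(
        Delta_T=g["Delta_T"], V_th_s=g["V_th_s"], V_th=g["V_th"],
        V_reset=g["V_reset"], t_ref=g["t_ref"], a=g["a"], b=g["b"],
        tau_w=g["tau_w"], g_w=g["g_w"], w_BAP=g["w_BAP"], d_BAP=g["d_BAP"],
    )
    hz = CaHotzoneMechanism(
        g_Ca=g["g_Ca"], E_Ca=g["E_Ca"], m_slope=g["m_slope"], m_half=g["m_half"],
        tau_m_Ca=g["tau_m_Ca"], h_slope=g["h_slope"], h_half=g["h_half"],
        tau_h_Ca=g["tau_h_Ca"], g_K=g["g_K"], E_K=g["E_K"],
        tau_m_KCa=g["tau_m_KCa"], Ca_th=g["Ca_th"], const_KCa=g["const_KCa"],
        phi_Ca=g["phi_Ca"], Ca_0=g["Ca_0"], tau_Ca=g["tau_Ca"],
    )
    soma = Compartment(id=0, parent=None, C_m=g["C_m_s"], g_L=g["g_L_s"],
                       E_L=g["E_L_s"], channels=[adex])
    distal = Compartment(id=1, parent=0, C_m=g["C_m_d"], g_L=g["g_L_d"],
                         E_L=g["E_L_d"], g_C=g["g_C"], channels=[hz])
    return build_tree([soma, distal])


def genome_to_dict(genome: Genome) -> dict:
    """Plain-dict form (values + bounds) for serialization."""
    return {"values": dict(genome.values),
            "bounds": {k: list(v) for k, v in genome.bounds.items()}}


def genome_from_dict(d: dict) -> Genome:
    if "values" not in d:
        raise ConfigurationError("genome dict must contain a 'values' map")
    bounds = {k: tuple(v) for k, v in d.get("bounds", DEFAULT_BOUNDS).items()}
    return Genome(values=dict(d["values"]), bounds=bounds)
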