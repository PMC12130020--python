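"""Time-stepping engine for compartment trees.

The membrane equation is discretized with the Crank-Nicolson scheme,

    C_i (V_i(t+h) - V_i(t)) / h = (F_i(V(t)) + F_i(V(t+h))) / 2,

where the only non-linear voltage term on the implicit side (the AdEx
spike-initiation exponential) is Taylor-expanded once around V(t) — a single
linearization and a single linear solve per step, no iteration.  The linear
system lives on the compartment tree and is solved exactly in O(N) by the
Hines algorithm.  Gating variables, the calcium pool and the adaptation
variable w are advanced by exact exponential propagators on a staggered
(leap-frog) grid: their values at t+h/2 enter both sides of the voltage
update, and they are then advanced by h using the freshly solved V(t+h).

Spikes are detected on the post-solve somatic voltage (V_s >= V_th); the
spike time is the end of the step.  V_s is then held at V_reset for t_ref
while every other compartment keeps integrating, b is added to w, and a
back-propagating action potential delivers the charge w_BAP into the distal
compartment d_BAP ms later, as a one-step current w_BAP/h (the delivered
charge is therefore independent of h).

The engine is batched: B independent instances of the same tree topology
(optionally with per-instance parameters and stimulus amplitudes) advance
in lock-step, each step performing a handful of numpy operations on (B,)
arrays per compartment.  ``simulate`` is the single-instance front end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .channels import (
    EXP_ARG_CLAMP,
    ReceptorSpec,
    double_exp_normalization,
    nmda_block,
    sigmoid_inf,
    kca_m_inf,
)
from .model import AdExMechanism, CaHotzoneMechanism, CompartmentTree

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "NumericalError",
    "StepCurrent",
    "BetaCurrent",
    "SpikeTrainInput",
    "PoissonInput",
    "hines_solve",
    "dense_from_tree_system",
    "Engine",
    "simulate",
]


class NumericalError(RuntimeError):
    """Integration failure (non-finite voltage or singular system)."""


@dataclass
class SolverConfig:
    """Time grid and recording selection.

    ``record`` may contain "V", "Ca", "gating", "w"; an empty tuple records
    only spikes and running extrema (fast path for large scans).
    """

    h: float = 0.1          # time step, ms
    T: float = 100.0        # total simulated time, ms
    record: tuple = ("V", "Ca", "gating", "w")

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.T < self.h:
            raise ValueError("T must be >= h")


@dataclass
class SimulationResult:
    """Recordings and spike data of a single simulation run."""

    times: np.ndarray                   # (n_rec,) ms
    voltages: Optional[np.ndarray]      # (n_rec, N) mV, or None
    calcium: Optional[np.ndarray]       # (n_rec,) mM (first hot zone)
    gating: Optional[dict]              # name -> (n_rec,)
    w: Optional[np.ndarray]             # (n_rec,)
    spike_times: list                   # ms, strictly increasing
    events_delivered: list              # audit: ("BAP", t_ms)
    v_max: np.ndarray                   # (N,) running max of V
    v_min: np.ndarray                   # (N,) running min of V
    max_mh: float                       # max over run of m_Ca*h_Ca
    max_Ca: float                       # max over run of [Ca]


# ---------------------------------------------------------------------------
# Stimulus sources


@dataclass
class StepCurrent:
    """Rectangular current injection into one compartment.

    ``amplitude`` (pA) may be a scalar or a (B,) array for batched runs.
    ``t_off = inf`` gives a DC current.
    """

    comp: int
    amplitude: object
    t_on: float = 0.0
    t_off: float = math.inf

    def current(self, t: float, B: int) -> np.ndarray:
        amp = np.broadcast_to(np.asarray(self.amplitude, float), (B,))
        if self.t_on <= t < self.t_off:
            return amp
        return np.zeros(B)


@dataclass
class BetaCurrent:
    """EPSP-shaped (normalized double-exponential) current injection.

    The waveform peaks at exactly ``peak`` pA, ``t_peak`` ms after
    ``onset``; it mimics the synaptic current of a single strong input and
    is the distal stimulus of the pulse (BAC-firing) task.
    """

    comp: int
    peak: object            # pA, scalar or (B,)
    onset: float = 0.0      # ms
    tau_r: float = 2.0      # ms
    tau_d: float = 12.0     # ms

    def current(self, t: float, B: int) -> np.ndarray:
        peak = np.broadcast_to(np.asarray(self.peak, float), (B,))
        dt = t - self.onset
        if dt < 0:
            return np.zeros(B)
        n = double_exp_normalization(self.tau_r, self.tau_d)
        return peak * n * (math.exp(-dt / self.tau_d) - math.exp(-dt / self.tau_r))


@dataclass
class SpikeTrainInput:
    """A receptor on a compartment driven by a fixed presynaptic spike train."""

    comp: int
    receptor: ReceptorSpec
    spike_times: Sequence[float]        # ms


@dataclass
class PoissonInput:
    """A receptor driven by a homogeneous Poisson spike train (engine RNG)."""

    comp: int
    receptor: ReceptorSpec
    rate: object                        # Hz, scalar or (B,)


# ---------------------------------------------------------------------------
# Hines solver


def hines_solve(parent: np.ndarray, diag: np.ndarray, off: np.ndarray,
                rhs: np.ndarray) -> np.ndarray:
    """Solve the symmetric tree-structured linear system in O(N).

    The system matrix has ``diag[..., i]`` on the diagonal and
    ``off[..., i]`` at (i, parent[i]) and (parent[i], i) (``off[..., 0]``
    is ignored).  Compartments must be in Hines order (children after
    parents).  Leading axes are batch axes.  Bitwise-deterministic.
    """
    diag = np.array(diag, float, copy=True)
    rhs = np.array(rhs, float, copy=True)
    off = np.asarray(off, float)
    N = diag.shape[-1]
    for i in range(N - 1, 0, -1):
        p = parent[i]
        d = diag[..., i]
        if np.any(d == 0.0):
            raise NumericalError(f"singular diagonal at compartment {i} during elimination")
        factor = off[..., i] / d
        diag[..., p] = diag[..., p] - factor * off[..., i]
        rhs[..., p] = rhs[..., p] - factor * rhs[..., i]
    if np.any(diag[..., 0] == 0.0):
        raise NumericalError("singular diagonal at compartment 0 (root)")
    x = np.empty_like(rhs)
    x[..., 0] = rhs[..., 0] / diag[..., 0]
    for i in range(1, N):
        x[..., i] = (rhs[..., i] - off[..., i] * x[..., parent[i]]) / diag[..., i]
    return x


def dense_from_tree_system(parent, diag, off) -> np.ndarray:
    """Dense matrix equivalent of a (non-batched) tree system, for oracles."""
    N = len(diag)
    A = np.zeros((N, N))
    for i in range(N):
        A[i, i] = diag[i]
        if i > 0:
            A[i, parent[i]] = off[i]
            A[parent[i], i] = off[i]
    return A


# ---------------------------------------------------------------------------
# Engine


def _b(x, B):
    """Broadcast a scalar or (B,) value to a float (B,) array."""
    return np.ascontiguousarray(np.broadcast_to(np.asarray(x, float), (B,)))


class _Receptor:
    """Compiled receptor: one or two double-exponential conductance windows."""

    def __init__(self, comp: int, spec: ReceptorSpec, h: float, B: int):
        self.comp = comp
        self.spec = spec
        self.is_current = spec.kind == "BETA_CURRENT"
        comps = []
        if spec.kind in ("AMPA", "GABA", "BETA_CURRENT"):
            comps.append((spec.tau_r, spec.tau_d, spec.e_r, 1.0, False))
        elif spec.kind == "NMDA":
            comps.append((spec.tau_r, spec.tau_d, spec.e_r, 1.0, True))
        elif spec.kind == "AMPA_NMDA":
            from .channels import RECEPTOR_DEFAULTS
            nm = RECEPTOR_DEFAULTS["NMDA"]
            comps.append((spec.tau_r, spec.tau_d, spec.e_r, 1.0, False))
            comps.append((nm["tau_r"], nm["tau_d"], nm["e_r"], spec.nmda_ratio, True))
        self.parts = []
        for tau_r, tau_d, e_r, scale, is_nmda in comps:
            self.parts.append({
                "P_r": math.exp(-h / tau_r), "P_d": math.exp(-h / tau_d),
                "e_r": e_r, "is_nmda": is_nmda,
                "amp": spec.w * scale * double_exp_normalization(tau_r, tau_d),
                "z_r": np.zeros(B), "z_d": np.zeros(B),
            })
        self.pending: dict = {}     # step index -> (B,) increments (in spike counts)

    def schedule(self, step: int, counts) -> None:
        if step in self.pending:
            self.pending[step] = self.pending[step] + counts
        else:
            self.pending[step] = np.array(counts, float)

    def g_parts(self):
        """Current window values, one (B,) array per component."""
        return [(p, p["z_d"] - p["z_r"]) for p in self.parts]

    def advance(self, step: int) -> None:
        counts = self.pending.pop(step, None)
        for p in self.parts:
            p["z_r"] *= p["P_r"]
            p["z_d"] *= p["P_d"]
            if counts is not None:
                p["z_r"] = p["z_r"] + p["amp"] * counts
                p["z_d"] = p["z_d"] + p["amp"] * counts


class Engine:
    """Batched Crank-Nicolson/Hines integrator for one tree topology.

    Parameters of compartments and mechanisms may be scalars or (B,)
    arrays, enabling population-parallel runs (transfer-function grids,
    GA populations, networks of identical neurons).
    """

    def __init__(self, tree: CompartmentTree, config: SolverConfig, B: int = 1,
                 sources: Sequence = (), seed: Optional[int] = None,
                 record_batch: Optional[int] = 0):
        self.tree = tree
        self.cfg = config
        self.B = B
        self.h = config.h
        self.n_steps = int(round(config.T / config.h))
        self.rng = np.random.default_rng(seed)
        N = tree.n
        self.N = N
        self.parent = np.array([0 if c.parent is None else c.parent
                                for c in tree.compartments], int)
        self.C_m = np.stack([_b(c.C_m, B) for c in tree.compartments])      # (N,B)
        self.g_L = np.stack([_b(c.g_L, B) for c in tree.compartments])
        self.E_L = np.stack([_b(c.E_L, B) for c in tree.compartments])
        self.g_C = np.stack([_b(c.g_C, B) for c in tree.compartments])      # edge to parent
        self.g_C[0] = 0.0

        # mechanisms
        self.adex: Optional[AdExMechanism] = None
        self.adex_comp = 0
        self.hz: Optional[CaHotzoneMechanism] = None
        self.hz_comp: Optional[int] = None
        for c in tree.compartments:
            for ch in c.channels:
                if isinstance(ch, AdExMechanism):
                    self.adex, self.adex_comp = ch, c.id
                elif isinstance(ch, CaHotzoneMechanism):
                    if self.hz is None:
                        self.hz, self.hz_comp = ch, c.id
                    else:
                        raise NotImplementedError("at most one Ca hot zone per tree")

        # state
        self.V = self.E_L.copy()                                            # (N,B)
        self.t = 0.0
        self.step_idx = 0
        if self.adex is not None:
            a = self.adex
            self.w = np.zeros(B)
            self.adex_gL = self.g_L[self.adex_comp]
            self.Delta_T = _b(a.Delta_T, B)
            self.V_th_s = _b(a.V_th_s, B)
            self.V_th = _b(a.V_th, B)
            self.V_reset = _b(a.V_reset, B)
            self.a_sub = _b(a.a, B)
            self.b_inc = _b(a.b, B)
            self.g_w = _b(a.g_w, B)
            self.tau_w = _b(a.tau_w, B)
            self.P_w = np.exp(-self.h / self.tau_w)
            self.refr_steps = np.asarray(np.rint(_b(a.t_ref, B) / self.h), int)
            self.w_BAP = _b(a.w_BAP, B)
            self.d_BAP_steps = np.asarray(np.rint(_b(a.d_BAP, B) / self.h), int)
        self.refr_left = np.zeros(B, int)
        self.bap_queue: dict = {}       # step index -> (B,) bool/float delivery mask

        if self.hz is not None:
            z = self.hz
            Vd0 = self.V[self.hz_comp]
            self.m_Ca = sigmoid_inf(Vd0, _b(z.m_slope, B), _b(z.m_half, B))
            self.h_Ca = sigmoid_inf(Vd0, _b(z.h_slope, B), _b(z.h_half, B))
            self.Ca = _b(z.Ca_0, B).copy()
            self.m_KCa = np.asarray(kca_m_inf(self.Ca, z), float).reshape(B).copy()
            self.P_mCa = np.exp(-self.h / _b(z.tau_m_Ca, B))
            self.P_hCa = np.exp(-self.h / _b(z.tau_h_Ca, B))
            self.P_mKCa = np.exp(-self.h / _b(z.tau_m_KCa, B))
            self.P_Ca = np.exp(-self.h / _b(z.tau_Ca, B))
            self.hz_gCa = _b(z.g_Ca, B)
            self.hz_ECa = _b(z.E_Ca, B)
            self.hz_gK = _b(z.g_K, B)
            self.hz_EK = _b(z.E_K, B)
            self.hz_m_slope = _b(z.m_slope, B)
            self.hz_m_half = _b(z.m_half, B)
            self.hz_h_slope = _b(z.h_slope, B)
            self.hz_h_half = _b(z.h_half, B)
            self.hz_phi = _b(z.phi_Ca, B)
            self.hz_Ca0 = _b(z.Ca_0, B)
            self.hz_tauCa = _b(z.tau_Ca, B)

        # stimuli
        self.current_sources = []
        self.receptors: list[_Receptor] = []
        self.poisson: list[tuple[int, np.ndarray]] = []   # (receptor index, rate (B,))
        for s in sources:
            if isinstance(s, (StepCurrent, BetaCurrent)):
                self.current_sources.append(s)
            elif isinstance(s, SpikeTrainInput):
                r = _Receptor(s.comp, s.receptor, self.h, B)
                for ts in s.spike_times:
                    # snap to grid; increments become visible at their key,
                    # so the window onset is exactly k*h
                    kk = int(round(ts / self.h))
                    if kk == 0:
                        for p in r.parts:
                            p["z_r"] += p["amp"]
                            p["z_d"] += p["amp"]
                    elif 0 < kk <= self.n_steps:
                        r.schedule(kk, np.ones(B))
                self.receptors.append(r)
            elif isinstance(s, PoissonInput):
                r = _Receptor(s.comp, s.receptor, self.h, B)
                self.receptors.append(r)
                self.poisson.append((len(self.receptors) - 1, _b(s.rate, B)))
            else:
                raise TypeError(f"unknown stimulus source {type(s).__name__}")

        # spike log and extrema
        self.spike_steps: list = []     # (step_idx, array of batch indices)
        self.events: list = []
        self.v_max = self.V.copy()
        self.v_min = self.V.copy()
        self.max_mh = np.zeros(B)
        self.max_Ca = self.Ca.copy() if self.hz is not None else np.zeros(B)
        self.on_step: Optional[Callable] = None

        # recordings (single batch element record_batch, or none)
        self.record_batch = record_batch if config.record else None
        if self.record_batch is not None:
            n_rec = self.n_steps + 1
            self.rec_t = np.arange(n_rec) * self.h
            self.rec = {}
            if "V" in config.record:
                self.rec["V"] = np.empty((n_rec, N))
            if "Ca" in config.record and self.hz is not None:
                self.rec["Ca"] = np.empty(n_rec)
            if "gating" in config.record and self.hz is not None:
                self.rec["m_Ca"] = np.empty(n_rec)
                self.rec["h_Ca"] = np.empty(n_rec)
                self.rec["m_KCa"] = np.empty(n_rec)
            if "w" in config.record and self.adex is not None:
                self.rec["w"] = np.empty(n_rec)
            self._record(0)

    # -- helpers -----------------------------------------------------------

    def _record(self, k: int) -> None:
        rb = self.record_batch
        if "V" in self.rec:
            self.rec["V"][k] = self.V[:, rb]
        if "Ca" in self.rec:
            self.rec["Ca"][k] = self.Ca[rb]
        if "m_Ca" in self.rec:
            self.rec["m_Ca"][k] = self.m_Ca[rb]
            self.rec["h_Ca"][k] = self.h_Ca[rb]
            self.rec["m_KCa"][k] = self.m_KCa[rb]
        if "w" in self.rec:
            self.rec["w"][k] = self.w[rb]

    def _injected(self, t: float) -> np.ndarray:
        """Summed injected currents (N,B) at time t."""
        I = np.zeros((self.N, self.B))
        for s in self.current_sources:
            I[s.comp] += s.current(t, self.B)
        return I

    # -- stepping ----------------------------------------------------------

    def step(self) -> None:
        """Advance the whole batch by one time step."""
        h, B, N = self.h, self.B, self.N
        k = self.step_idx
        t0 = k * h
        t1 = t0 + h

        I_t = self._injected(t0)
        I_tp = self._injected(t1)

        # BAP charge: one-step rectangular current w_BAP/h into the hot zone
        bap = self.bap_queue.pop(k, None)
        if bap is not None and self.hz_comp is not None:
            I_bap = self.w_BAP / h * bap
            I_t[self.hz_comp] += I_bap
            I_tp[self.hz_comp] += I_bap
            for bi in np.flatnonzero(bap):
                self.events.append(("BAP", t0, int(bi)))

        # Poisson receptor spike generation for this step
        for ridx, rate in self.poisson:
            counts = self.rng.poisson(rate * h * 1e-3, size=B)
            if np.any(counts):
                self.receptors[ridx].schedule(k + 1, counts.astype(float))

        # conductance-like channel terms (gating frozen at t+h/2)
        g_sum = np.zeros((N, B))        # conductances on the implicit side
        gE_t = np.zeros((N, B))         # explicit-side currents g*(E - V(t))
        gE_tp = np.zeros((N, B))        # implicit-side g*E (diag gets g)
        if self.hz is not None:
            i = self.hz_comp
            g1 = self.hz_gCa * self.m_Ca * self.h_Ca
            g2 = self.hz_gK * self.m_KCa
            g_sum[i] += g1 + g2
            gE_t[i] += g1 * (self.hz_ECa - self.V[i]) + g2 * (self.hz_EK - self.V[i])
            gE_tp[i] += g1 * self.hz_ECa + g2 * self.hz_EK

        # synaptic receptors: value at t on the explicit side, advanced value
        # at t+h on the implicit side (window value at its own onset is 0)
        for r in self.receptors:
            parts_t = [(p, g.copy()) for p, g in r.g_parts()]
            r.advance(k + 1)
            for (p, g_t), (_, g_tp) in zip(parts_t, r.g_parts()):
                if r.is_current:
                    I_t[r.comp] += g_t
                    I_tp[r.comp] += g_tp
                    continue
                if p["is_nmda"]:
                    sig = nmda_block(self.V[r.comp])
                    g_t = g_t * sig
                    g_tp = g_tp * sig
                g_sum[r.comp] += g_tp
                gE_t[r.comp] += g_t * (p["e_r"] - self.V[r.comp])
                gE_tp[r.comp] += g_tp * p["e_r"]

        # AdEx exponential (Taylor-linearized) and adaptation current
        phi = np.zeros((N, B))
        dphi = np.zeros((N, B))
        I_w = np.zeros((N, B))
        if self.adex is not None:
            i = self.adex_comp
            arg = (self.V[i] - self.V_th_s) / self.Delta_T
            arg = np.minimum(arg, EXP_ARG_CLAMP)
            phi_i = self.adex_gL * self.Delta_T * np.exp(arg)
            phi[i] = phi_i
            # cap the Taylor derivative at C/h: keeps the CN diagonal
            # positive during spike runaway (the explicit exponential term
            # still drives the voltage up); spike detection is at V_th
            dphi_i = np.where(arg < EXP_ARG_CLAMP, phi_i / self.Delta_T, 0.0)
            dphi[i] = np.minimum(dphi_i, self.C_m[i] / h)
            I_w[i] = -self.g_w * self.w

        # coupling sums at t: sum_j g_C (V_j - V_i)
        coup_t = np.zeros((N, B))
        for i in range(1, N):
            p = self.parent[i]
            flow = self.g_C[i] * (self.V[p] - self.V[i])
            coup_t[i] += flow
            coup_t[p] -= flow

        # assemble CN system: (N,B) diag/off/rhs
        g_edge_sum = np.zeros((N, B))
        for i in range(1, N):
            g_edge_sum[i] += self.g_C[i]
            g_edge_sum[self.parent[i]] += self.g_C[i]

        F_t = (self.g_L * (self.E_L - self.V) + gE_t + coup_t + I_t + phi + I_w)
        diag = (self.C_m / h + 0.5 * (self.g_L + g_sum + g_edge_sum) - 0.5 * dphi)
        off = -0.5 * self.g_C        # row i, column parent[i]
        rhs = (self.C_m / h * self.V + 0.5 * F_t
               + 0.5 * (self.g_L * self.E_L + gE_tp + I_tp + phi - dphi * self.V + I_w))

        # refractory clamp: soma (root) voltage is a known constant
        clamped = self.refr_left > 0
        if np.any(clamped):
            s = self.adex_comp
            for i in range(1, N):
                if self.parent[i] == s:
                    rhs[i, clamped] -= off[i, clamped] * self.V_reset[clamped]
            off_mod = off.copy()
            for i in range(1, N):
                if self.parent[i] == s:
                    off_mod[i, clamped] = 0.0
            diag = diag.copy()
            rhs = rhs.copy()
            diag[s, clamped] = 1.0
            rhs[s, clamped] = self.V_reset[clamped]
            off = off_mod

        V_new = hines_solve(self.parent, diag.T, off.T, rhs.T).T     # (N,B)
        if not np.all(np.isfinite(V_new)):
            bad = np.argwhere(~np.isfinite(V_new))
            ci, bi = int(bad[0][0]), int(bad[0][1])
            raise NumericalError(
                f"non-finite voltage at step {k + 1} (t={t1:.3f} ms), "
                f"compartment {ci}, batch element {bi}"
            )

        # gating / calcium updates using V(t+h)
        if self.hz is not None:
            i = self.hz_comp
            Vd = V_new[i]
            m_inf = sigmoid_inf(Vd, self.hz_m_slope, self.hz_m_half)
            h_inf = sigmoid_inf(Vd, self.hz_h_slope, self.hz_h_half)
            self.m_Ca = self.P_mCa * self.m_Ca + (1.0 - self.P_mCa) * m_inf
            self.h_Ca = self.P_hCa * self.h_Ca + (1.0 - self.P_hCa) * h_inf
            I_Ca = self.hz_gCa * self.m_Ca * self.h_Ca * (self.hz_ECa - Vd)
            Ca_ss = self.hz_Ca0 + self.hz_phi * I_Ca * self.hz_tauCa
            self.Ca = Ca_ss + (self.Ca - Ca_ss) * self.P_Ca
            mK_inf = 1.0 / (1.0 + (self.hz.Ca_th / np.maximum(self.Ca, 1e-300))
                            ** self.hz.const_KCa)
            self.m_KCa = self.P_mKCa * self.m_KCa + (1.0 - self.P_mKCa) * mK_inf
            np.maximum(self.max_mh, self.m_Ca * self.h_Ca, out=self.max_mh)
            np.maximum(self.max_Ca, self.Ca, out=self.max_Ca)

        spiking = np.zeros(self.B, bool)
        if self.adex is not None:
            s = self.adex_comp
            # w: exponential integration with V_s fixed at its new value
            w_inf = self.a_sub * (V_new[s] - self.E_L[s])
            self.w = w_inf + (self.w - w_inf) * self.P_w
            self.refr_left = np.maximum(self.refr_left - 1, 0)
            spiking = (V_new[s] >= self.V_th) & ~clamped
            if np.any(spiking):
                idx = np.flatnonzero(spiking)
                V_new[s, idx] = self.V_reset[idx]
                self.w[idx] += self.b_inc[idx]
                self.refr_left[idx] = self.refr_steps[idx]
                self.spike_steps.append((k + 1, idx))
                if self.hz_comp is not None and np.any(self.w_BAP[idx] != 0.0):
                    for d in np.unique(self.d_BAP_steps[idx]):
                        sub = idx[self.d_BAP_steps[idx] == d]
                        tgt = k + 1 + int(d)
                        mask = self.bap_queue.setdefault(tgt, np.zeros(self.B))
                        mask[sub] += 1.0
            V_new[s, clamped] = self.V_reset[clamped]

        self.V = V_new
        np.maximum(self.v_max, V_new, out=self.v_max)
        np.minimum(self.v_min, V_new, out=self.v_min)
        self.step_idx = k + 1
        self.t = t1
        if self.record_batch is not None:
            self._record(k + 1)
        if self.on_step is not None:
            self.on_step(self, k + 1, spiking)

    def run(self) -> None:
        for _ in range(self.n_steps):
            self.step()

    # -- outputs -----------------------------------------------------------

    def spike_times_per_batch(self) -> list:
        """List of B arrays of spike times in ms."""
        out = [[] for _ in range(self.B)]
        for k, idx in self.spike_steps:
            t = k * self.h
            for bi in idx:
                out[int(bi)].append(t)
        return [np.asarray(x) for x in out]

    def spike_counts(self) -> np.ndarray:
        counts = np.zeros(self.B, int)
        for _, idx in self.spike_steps:
            counts[idx] += 1
        return counts

    def result(self) -> SimulationResult:
        """Package recordings of batch element ``record_batch`` (default 0)."""
        rb = self.record_batch if self.record_batch is not None else 0
        spikes = list(self.spike_times_per_batch()[rb])
        gating = None
        if self.record_batch is not None and "m_Ca" in self.rec:
            gating = {k: self.rec[k] for k in ("m_Ca", "h_Ca", "m_KCa")}
        return SimulationResult(
            times=self.rec_t if self.record_batch is not None else None,
            voltages=self.rec.get("V") if self.record_batch is not None else None,
            calcium=self.rec.get("Ca") if self.record_batch is not None else None,
            gating=gating,
            w=self.rec.get("w") if self.record_batch is not None else None,
            spike_times=spikes,
            events_delivered=[e for e in self.events if e[2] == rb],
            v_max=self.v_max[:, rb].copy(),
            v_min=self.v_min[:, rb].copy(),
            max_mh=float(self.max_mh[rb]),
            max_Ca=float(self.max_Ca[rb]),
        )


def simulate(tree: CompartmentTree, program: Sequence, config: SolverConfig,
             seed: Optional[int] = None) -> SimulationResult:
    """Run one simulation of ``tree`` under the given stimulus program.

    ``program`` is a sequence of stimulus sources (:class:`StepCurrent`,
    :class:`BetaCurrent`, :class:`SpikeTrainInput`, :class:`PoissonInput`).
    Deterministic for a fixed seed; the seed is consumed only by stochastic
    inputs.
    """
    eng = Engine(tree, config, B=1, sources=program, seed=seed)
    eng.run()
    return eng.result()
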