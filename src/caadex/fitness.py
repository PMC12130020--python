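"""Fitness functions guiding the evolutionary fit of the Ca-AdEx genome.

Every component maps a measured error onto a bounded score
``exp(-|error|/scale)`` in (0, 1], with one documented scale per
component, so the global fitness — the plain sum of all components — is
well defined and maximal when every target behaviour is met exactly.
Components fall into five groups:

* pulse task: correct spike counts in the four BAC-firing cases;
* calcium behaviour: the channel opens and closes when it should, never
  with purely somatic input, and not only at extreme currents;
* AdEx matching: the I_d = 0 response matches a reference
  single-compartment AdEx neuron (Earth Mover's Distance between rate
  curves, rheobase, final rate, CV of ISIs, total capacitance);
* gain & linearity: post-activation rate level, planarity of the active
  region, monotonicity in I_s, presence of the activation jump;
* guards: pathological firing rates, somatic voltage floor, distal
  rheobase window, missing rate jump.

A simulation failure scores the documented worst value instead of
aborting the evolutionary run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Genome, build_two_compartment
from .protocols import (
    PulseTaskSpec,
    TransferSurface,
    run_prolonged_scan,
    run_pulse_task,
    spike_stats,
)
from .solver import Engine, SolverConfig, StepCurrent

__all__ = [
    "FitnessReport",
    "FitnessProtocol",
    "emd_1d",
    "pulse_fitness",
    "adex_matching_fitness",
    "gain_linearity_fitness",
    "guard_fitness",
    "evaluate_genome",
    "WORST_FITNESS",
]

#: Score assigned to a genome whose simulation fails (worst possible).
WORST_FITNESS = 0.0


def _score(err: float, scale: float) -> float:
    """Bounded component score exp(-|err|/scale) in (0, 1]."""
    return math.exp(-abs(err) / scale)


def emd_1d(u, v, dx: float = 1.0) -> float:
    """1-D Earth Mover's (Wasserstein-1) distance between two curves.

    Both curves are treated as mass distributions over the same equispaced
    grid: they are normalized to unit mass and the distance is the L1
    difference of their cumulative sums times the grid spacing ``dx``.
    Two all-zero curves have distance 0 by convention.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("emd_1d requires equal-length sequences")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("emd_1d requires non-negative values")
    su, sv = u.sum(), v.sum()
    if su == 0 and sv == 0:
        return 0.0
    if su == 0 or sv == 0:
        # all mass of one curve is missing; transport is undefined, use the
        # maximal displacement as a conservative penalty
        return float(dx * (len(u) - 1))
    cu = np.cumsum(u / su)
    cv = np.cumsum(v / sv)
    return float(dx * np.sum(np.abs(cu - cv)))


@dataclass
class FitnessReport:
    """Named component scores; ``global_fitness`` is their exact sum."""

    components: dict = field(default_factory=dict)

    @property
    def global_fitness(self) -> float:
        return float(sum(self.components.values()))

    def __getitem__(self, name: str) -> float:
        return self.components[name]


def pulse_fitness(report) -> dict:
    """Four scores for the pulse-task cases (targets A:0, B:1, C:3, D:burst)."""
    targets = {"A": 0, "B": 1, "C": 3}
    out = {}
    for case, target in targets.items():
        out[f"pulse_case{case}"] = _score(report.cases[case].spike_count - target, 1.0)
    d = report.cases["D"]
    out["pulse_caseD"] = 1.0 if d.is_burst else _score(1 + abs(d.spike_count - 2), 1.0)
    return out


def adex_matching_fitness(Is_grid, rates, ref_rates, cv: Optional[float],
                          ref_cv: Optional[float], capacitance: float,
                          ref_capacitance: float) -> dict:
    """Five scores comparing the I_d = 0 response with a reference AdEx.

    ``rates`` and ``ref_rates`` must be sampled on the same I_s grid.
    The rheobase is the first grid current with a non-zero rate.
    """
    Is_grid = np.asarray(Is_grid, float)
    rates = np.asarray(rates, float)
    ref_rates = np.asarray(ref_rates, float)
    if rates.shape != ref_rates.shape or rates.shape != Is_grid.shape:
        raise ValueError("rate curves and grid must share one shape")
    dx = float(Is_grid[1] - Is_grid[0]) if len(Is_grid) > 1 else 1.0
    emd = emd_1d(rates, ref_rates, dx)

    def rheo(r):
        nz = np.flatnonzero(r > 0)
        return Is_grid[nz[0]] if nz.size else Is_grid[-1] + dx

    d_rheo = rheo(rates) - rheo(ref_rates)
    d_last = rates[-1] - ref_rates[-1]
    d_cv = 0.0 if (cv is None or ref_cv is None) else cv - ref_cv
    d_cap = capacitance - ref_capacitance
    return {
        "adex_emd": _score(emd, 50.0),          # pA of transported mass
        "adex_rheobase": _score(d_rheo, 50.0),  # pA
        "adex_last_rate": _score(d_last, 10.0), # Hz
        "adex_cv_isi": _score(d_cv, 0.25),
        "capacitance_match": _score(d_cap, 100.0),  # pF
    }


def gain_linearity_fitness(surface: TransferSurface,
                           distal_rate_target: float = 30.0) -> dict:
    """Scores for the apical-gain region: level, planarity, monotonicity."""
    act = surface.ca_active
    rate = surface.rate
    # distal-only firing level right after Ca opening
    col0 = act[0]
    if np.any(col0):
        r0 = rate[0, np.argmax(col0)]
        distal_level = _score(r0 - distal_rate_target, 20.0)
    else:
        distal_level = WORST_FITNESS
    # linearity: R^2 of a straight line along each active row (>=3 points)
    r2s = []
    for i in range(rate.shape[0]):
        idx = np.flatnonzero(act[i])
        if idx.size >= 3:
            y = rate[i, idx]
            x = surface.Id_grid[idx]
            p = np.polyfit(x, y, 1)
            ss_res = np.sum((y - np.polyval(p, x)) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2s.append(1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot)
    linearity = float(np.mean(r2s)) if r2s else WORST_FITNESS
    # monotonicity of nu(I_s) at fixed I_d (violations beyond 0.5 Hz slack)
    viol = int(np.sum(np.diff(rate, axis=0) < -0.5))
    # fraction of I_s columns where the activation jump exists
    jump_frac = float(np.mean(np.any(act, axis=1)))
    return {
        "distal_only_rate": distal_level,
        "gain_linearity": linearity,
        "monotonicity": _score(viol, 3.0),
        "gain_presence": jump_frac,
    }


def guard_fitness(surface: TransferSurface, min_Vs: float,
                  rate_cap: float = 200.0, v_floor: float = -90.0,
                  distal_rheobase: Optional[float] = None,
                  rheobase_window=(300.0, 700.0),
                  jump_min: float = 5.0) -> dict:
    """Exclusion guards; each score is 1 when the guard is satisfied."""
    act = surface.ca_active
    rate = surface.rate
    somatic_only_ok = not np.any(act[:, 0])
    ca_ever = bool(np.any(act))
    # calcium must also close: at least one inactive point must exist
    ca_closes = bool(np.any(~act))
    over = float(max(0.0, rate.max() - rate_cap))
    vs_under = float(max(0.0, v_floor - min_Vs))
    if distal_rheobase is None:
        rheo_ok = 0.0
    else:
        lo, hi = rheobase_window
        rheo_ok = 1.0 if lo <= distal_rheobase <= hi else _score(
            min(abs(distal_rheobase - lo), abs(distal_rheobase - hi)), 100.0)
    # rate jump across the activation boundary on the distal-only column
    col = act[0]
    if np.any(col) and np.argmax(col) > 0:
        j = np.argmax(col)
        jump = rate[0, j] - rate[0, j - 1]
        jump_ok = 1.0 if jump >= jump_min else _score(jump_min - jump, 5.0)
    else:
        jump_ok = 0.0
    return {
        "no_ca_somatic_only": 1.0 if somatic_only_ok else 0.0,
        "ca_opens": 1.0 if ca_ever else 0.0,
        "ca_closes": 1.0 if ca_closes else 0.0,
        "no_ca_at_high_I": 1.0 if ca_ever and not np.all(act[:, -1] & act[:, 0]) else 0.0,
        "pathological_rate": _score(over, 20.0),
        "min_Vs": _score(vs_under, 5.0),
        "distal_rheobase": rheo_ok,
        "rate_jump": jump_ok,
    }


@dataclass
class FitnessProtocol:
    """Grids and references used to score a genome.

    The default working domain is I_s in [0, 600] pA, I_d in [0, 1000] pA.
    Coarser grids make GA generations affordable; the acceptance runs state
    their own resolution.
    """

    Is_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 601.0, 100.0))
    Id_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 1001.0, 100.0))
    stim_ms: float = 1000.0
    h: float = 0.1
    pulse: PulseTaskSpec = field(default_factory=PulseTaskSpec)
    ref_rates: Optional[np.ndarray] = None      # reference AdEx rates on Is_grid
    ref_cv: Optional[float] = None
    ref_capacitance: float = 640.0              # pF, C_m_s + C_m_d of the reference
    cv_at_index: int = -1                       # I_s index for the CV comparison


def reference_protocol(Is_step: float = 100.0, Id_step: float = 200.0,
                       stim_ms: float = 1000.0) -> FitnessProtocol:
    """Protocol with the reference single-compartment AdEx as the target.

    The target AdEx (shipped with the package) is simulated on the somatic
    current grid to provide the rate curve, CV and capacitance references
    for the AdEx-matching components.
    """
    from . import target_adex_parameters
    from .model import AdExMechanism, Compartment, build_tree

    tgt = target_adex_parameters()
    soma = Compartment(id=0, parent=None, C_m=tgt["C_m_s"], g_L=tgt["g_L_s"],
                       E_L=tgt["E_L_s"],
                       channels=[AdExMechanism(
                           Delta_T=tgt["Delta_T"], V_th_s=tgt["V_th_s"],
                           V_th=tgt["V_th"], V_reset=tgt["V_reset"],
                           t_ref=tgt["t_ref"], a=tgt["a"], b=tgt["b"],
                           tau_w=tgt["tau_w"], g_w=tgt["g_w"])])
    tree = build_tree([soma])
    Is_grid = np.arange(0.0, 600.0 + Is_step / 2, Is_step)
    eng = Engine(tree, SolverConfig(h=0.1, T=stim_ms, record=()),
                 B=len(Is_grid), sources=[StepCurrent(0, Is_grid)])
    eng.run()
    ref_rates = eng.spike_counts() / (stim_ms * 1e-3)
    ref_cv = spike_stats(eng.spike_times_per_batch()[-1], stim_ms)["cv_isi"]
    return FitnessProtocol(
        Is_grid=Is_grid,
        Id_grid=np.arange(0.0, 1000.0 + Id_step / 2, Id_step),
        stim_ms=stim_ms, ref_rates=ref_rates, ref_cv=ref_cv,
        ref_capacitance=tgt["C_m_s"])


def evaluate_genome(genome: Genome, protocol: Optional[FitnessProtocol] = None
                    ) -> FitnessReport:
    """Score one genome with the full fitness suite.

    Any simulation failure yields a report whose components are all
    :data:`WORST_FITNESS`.
    """
    if protocol is None:
        protocol = FitnessProtocol()
    names = ["pulse_caseA", "pulse_caseB", "pulse_caseC", "pulse_caseD",
             "ca_opens", "ca_closes", "no_ca_somatic_only", "no_ca_at_high_I",
             "adex_emd", "adex_rheobase", "adex_last_rate", "adex_cv_isi",
             "capacitance_match", "distal_only_rate", "gain_linearity",
             "monotonicity", "gain_presence", "pathological_rate", "min_Vs",
             "distal_rheobase", "rate_jump"]
    try:
        tree = build_two_compartment(genome)
        cfg = SolverConfig(h=protocol.h, T=150.0, record=("V",))
        pulse_rep = run_pulse_task(tree, protocol.pulse, cfg)
        surface = run_prolonged_scan(tree, protocol.Is_grid, protocol.Id_grid,
                                     SolverConfig(h=protocol.h, T=protocol.stim_ms,
                                                  record=()),
                                     stim_ms=protocol.stim_ms)
        # distal-only rheobase and spike train at the CV comparison current
        eng = Engine(tree, SolverConfig(h=protocol.h, T=protocol.stim_ms, record=()),
                     B=len(protocol.Id_grid),
                     sources=[StepCurrent(1, np.asarray(protocol.Id_grid))])
        eng.run()
        counts = eng.spike_counts()
        dr = (float(protocol.Id_grid[np.argmax(counts > 0)])
              if np.any(counts > 0) else None)
        min_Vs = float(eng.v_min[0].min())

        comps = {}
        comps.update(pulse_fitness(pulse_rep))
        if protocol.ref_rates is not None:
            eng_s = Engine(tree, SolverConfig(h=protocol.h, T=protocol.stim_ms,
                                              record=()),
                           B=len(protocol.Is_grid),
                           sources=[StepCurrent(0, np.asarray(protocol.Is_grid))])
            eng_s.run()
            row0 = eng_s.spike_counts() / (protocol.stim_ms * 1e-3)
            st = eng_s.spike_times_per_batch()[protocol.cv_at_index]
            cv = spike_stats(st, protocol.stim_ms)["cv_isi"]
            cap = genome["C_m_s"] + genome["C_m_d"]
            comps.update(adex_matching_fitness(
                protocol.Is_grid, row0, protocol.ref_rates, cv, protocol.ref_cv,
                cap, protocol.ref_capacitance))
        else:
            comps.update({k: WORST_FITNESS for k in
                          ("adex_emd", "adex_rheobase", "adex_last_rate",
                           "adex_cv_isi", "capacitance_match")})
        comps.update(gain_linearity_fitness(surface))
        comps.update(guard_fitness(surface, min_Vs, distal_rheobase=dr))
        return FitnessReport(components=comps)
    except Exception:
        return FitnessReport(components={n: WORST_FITNESS for n in names})
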