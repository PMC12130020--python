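"""Stimulation protocols: pulse (BAC-firing) task, DC transfer-function
scans, Poisson-input scans, and spike-train statistics.

The pulse task probes coincidence detection with four cases:

  A. a subthreshold EPSP-shaped (beta) current into the distal compartment
     — deflects the soma without spiking;
  B. a brief just-suprathreshold somatic step — exactly one spike;
  C. B followed by A after a short delay — BAC firing, a somatic burst;
  D. a distal-only beta current strong enough to evoke a burst by itself.

The prolonged task holds DC current pairs (I_s, I_d) constant for a couple
of seconds and measures the firing rate nu(I_s, I_d) plus a per-point flag
for dendritic Ca2+-channel activation, producing the transfer surface that
ThetaPlanes approximates.  Every grid point is an independent simulation
started from rest, so the points are batched and run in lock-step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import CompartmentTree, ConfigurationError
from .channels import ReceptorSpec
from .solver import (
    BetaCurrent,
    Engine,
    PoissonInput,
    SolverConfig,
    SimulationResult,
    StepCurrent,
    simulate,
)

__all__ = [
    "PulseTaskSpec",
    "PulseTaskReport",
    "TransferSurface",
    "run_pulse_task",
    "find_burst_threshold",
    "run_prolonged_scan",
    "detect_ca_activation",
    "spike_stats",
    "run_poisson_scan",
]


@dataclass
class PulseTaskSpec:
    """Stimulus amplitudes and timing of the four-case pulse task."""

    somatic_amplitude: float = 1150.0   # pA
    somatic_duration: float = 5.0       # ms
    distal_peak: float = 1345.0         # pA, beta-current peak (cases A, C)
    delay: float = 5.0                  # ms, somatic onset -> distal onset
    burst_peak: float = 1830.0          # pA, strong distal-only case D
    beta_tau_r: float = 2.0             # ms
    beta_tau_d: float = 8.0             # ms
    onset: float = 20.0                 # ms, somatic stimulus onset
    burst_max_isi: float = 25.0         # ms, first ISI must be below this

    def __post_init__(self) -> None:
        if self.somatic_duration <= 0:
            raise ConfigurationError("somatic_duration must be > 0")
        if self.delay < 0:
            raise ConfigurationError("delay must be >= 0")


@dataclass
class PulseCaseResult:
    spike_count: int
    somatic_deflection: float           # mV, peak deviation of V_s from rest
    spike_times: list
    is_burst: bool


@dataclass
class PulseTaskReport:
    cases: dict                         # "A".."D" -> PulseCaseResult


def _is_burst(spike_times: Sequence[float], max_isi: float) -> bool:
    st = np.asarray(spike_times, float)
    return len(st) >= 2 and (st[1] - st[0]) < max_isi


def run_pulse_task(tree: CompartmentTree, spec: PulseTaskSpec,
                   config: Optional[SolverConfig] = None) -> PulseTaskReport:
    """Run the four pulse-task cases and report counts and deflections.

    The somatic deflection is the peak deviation of V_s from its value at
    stimulus onset (the neuron rests for ``spec.onset`` ms first).
    """
    if config is None:
        config = SolverConfig(h=0.1, T=200.0, record=("V",))
    t_on = spec.onset
    t_beta = t_on + spec.delay
    beta = dict(tau_r=spec.beta_tau_r, tau_d=spec.beta_tau_d)
    programs = {
        "A": [BetaCurrent(1, spec.distal_peak, onset=t_beta, **beta)],
        "B": [StepCurrent(0, spec.somatic_amplitude, t_on, t_on + spec.somatic_duration)],
        "C": [StepCurrent(0, spec.somatic_amplitude, t_on, t_on + spec.somatic_duration),
              BetaCurrent(1, spec.distal_peak, onset=t_beta, **beta)],
        "D": [BetaCurrent(1, spec.burst_peak, onset=t_beta, **beta)],
    }
    cases = {}
    onset_idx = int(round(t_on / config.h))
    for name, program in programs.items():
        res = simulate(tree, program, config)
        v_rest = res.voltages[onset_idx, 0]
        cases[name] = PulseCaseResult(
            spike_count=len(res.spike_times),
            somatic_deflection=float(res.v_max[0] - v_rest),
            spike_times=list(res.spike_times),
            is_burst=_is_burst(res.spike_times, spec.burst_max_isi),
        )
    return PulseTaskReport(cases=cases)


def find_burst_threshold(tree: CompartmentTree, spec: PulseTaskSpec,
                         config: Optional[SolverConfig] = None,
                         lo: float = 1000.0, hi: float = 2500.0,
                         step: float = 10.0) -> Optional[float]:
    """Minimal distal-only beta peak (pA) evoking a burst, on a current grid.

    All candidate amplitudes run as one batch; returns ``None`` if no
    amplitude in [lo, hi] produces a burst.
    """
    if config is None:
        config = SolverConfig(h=0.1, T=200.0, record=())
    amps = np.arange(lo, hi + 0.5 * step, step)
    program = [BetaCurrent(1, amps, onset=spec.onset + spec.delay,
                           tau_r=spec.beta_tau_r, tau_d=spec.beta_tau_d)]
    eng = Engine(tree, config, B=len(amps), sources=program)
    eng.run()
    for amp, st in zip(amps, eng.spike_times_per_batch()):
        if _is_burst(st, spec.burst_max_isi):
            return float(amp)
    return None


@dataclass
class TransferSurface:
    """Firing-rate grid nu(I_s, I_d) with per-point Ca-activation flags."""

    Is_grid: np.ndarray                 # (nIs,) pA, strictly increasing
    Id_grid: np.ndarray                 # (nId,) pA, strictly increasing
    rate: np.ndarray                    # (nIs, nId) Hz
    ca_active: np.ndarray               # (nIs, nId) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Is_grid = np.asarray(self.Is_grid, float)
        self.Id_grid = np.asarray(self.Id_grid, float)
        if np.any(np.diff(self.Is_grid) <= 0) or np.any(np.diff(self.Id_grid) <= 0):
            raise ConfigurationError("current grids must be strictly increasing")
        if np.any(np.asarray(self.rate) < 0):
            raise ConfigurationError("firing rates must be non-negative")


#: Default Ca-activation criteria (see ``detect_ca_activation``).
GATING_THRESHOLD = 0.5
CALCIUM_FRACTION = 0.5


def _ca_flags(max_mh: np.ndarray, max_Ca: np.ndarray, hz,
              criterion: str) -> np.ndarray:
    if criterion == "gating":
        return max_mh >= GATING_THRESHOLD
    if criterion == "calcium":
        return max_Ca >= hz.Ca_0 + CALCIUM_FRACTION * (hz.Ca_th - hz.Ca_0)
    raise ConfigurationError(f"unknown Ca-activation criterion '{criterion}'")


def detect_ca_activation(result: SimulationResult, tree: CompartmentTree,
                         criterion: str = "gating") -> bool:
    """Did the high-voltage-activated Ca2+ channel open during the run?

    ``gating``: the activation product m_Ca*h_Ca exceeded 0.5 at some point.
    ``calcium``: the Ca concentration rose at least halfway from baseline
    Ca_0 to the K_Ca half-activation threshold Ca_th.
    """
    hz_idx = tree.hotzone_index()
    if hz_idx is None:
        raise ConfigurationError("tree has no Ca hot zone")
    hz = next(ch for ch in tree.compartments[hz_idx].channels
              if hasattr(ch, "Ca_th"))
    return bool(_ca_flags(np.asarray(result.max_mh), np.asarray(result.max_Ca),
                          hz, criterion))


def run_prolonged_scan(tree: CompartmentTree, Is_grid, Id_grid,
                       config: Optional[SolverConfig] = None,
                       stim_ms: float = 2000.0,
                       criterion: str = "gating") -> TransferSurface:
    """DC transfer-function scan over the (I_s, I_d) grid.

    Each grid point is an independent 2-s (by default) constant-current
    simulation from rest; the rate is the spike count divided by the
    stimulus duration (no transient exclusion).  Points are batched into a
    single lock-step run.  The inter-stimulus rest period of the wet-lab
    protocol carries no information here because points do not share state.
    """
    Is_grid = np.asarray(Is_grid, float)
    Id_grid = np.asarray(Id_grid, float)
    if Is_grid.size == 0 or Id_grid.size == 0:
        raise ConfigurationError("current grids must be non-empty")
    if config is None:
        config = SolverConfig(h=0.1, T=stim_ms, record=())
    else:
        config = SolverConfig(h=config.h, T=stim_ms, record=())
    II_s, II_d = np.meshgrid(Is_grid, Id_grid, indexing="ij")
    B = II_s.size
    program = [StepCurrent(0, II_s.ravel()), StepCurrent(1, II_d.ravel())]
    eng = Engine(tree, config, B=B, sources=program)
    eng.run()
    rate = eng.spike_counts().reshape(II_s.shape) / (stim_ms * 1e-3)
    hz_idx = tree.hotzone_index()
    if hz_idx is not None:
        hz = next(ch for ch in tree.compartments[hz_idx].channels
                  if hasattr(ch, "Ca_th"))
        flags = _ca_flags(eng.max_mh, eng.max_Ca, hz, criterion).reshape(II_s.shape)
    else:
        flags = np.zeros(II_s.shape, bool)
    return TransferSurface(Is_grid=Is_grid, Id_grid=Id_grid, rate=rate,
                           ca_active=flags,
                           meta={"stim_ms": stim_ms, "h": config.h,
                                 "criterion": criterion})


def spike_stats(spike_times: Sequence[float], window: float) -> dict:
    """Rate, mean inter-spike interval and CV of ISIs over a window (ms).

    The CV (and mean ISI) are reported as ``None`` for fewer than 3 spikes.
    """
    if window <= 0:
        raise ConfigurationError("window must be > 0")
    st = np.asarray(spike_times, float)
    rate = len(st) / (window * 1e-3)
    if len(st) < 3:
        return {"rate": rate, "mean_isi": None, "cv_isi": None}
    isi = np.diff(st)
    mean = float(np.mean(isi))
    cv = float(np.std(isi) / mean) if mean > 0 else None
    return {"rate": rate, "mean_isi": mean, "cv_isi": cv}


def run_poisson_scan(tree: CompartmentTree, apical_rates, basal_rates,
                     apical_comps: Sequence[int], basal_comps: Sequence[int],
                     config: Optional[SolverConfig] = None,
                     gaba_rate: float = 20.0, episodes: int = 5,
                     episode_ms: float = 2000.0, weight: float = 1.0,
                     seed: Optional[int] = 0) -> dict:
    """Poisson-input scan for extended trees with AMPA+NMDA synapses.

    Every (apical rate, basal rate) pair is simulated for ``episodes``
    episodes of ``episode_ms``; each listed compartment carries one
    glutamatergic (AMPA+NMDA, NMDA ratio 2) and one GABAergic synapse, the
    latter driven at a fixed ``gaba_rate``.  Returns the mean output rate
    grid and mean compartment voltages.
    """
    apical_rates = np.asarray(apical_rates, float)
    basal_rates = np.asarray(basal_rates, float)
    if np.any(apical_rates < 0) or np.any(basal_rates < 0):
        raise ConfigurationError("input rates must be >= 0")
    if config is None:
        config = SolverConfig(h=0.1, T=episode_ms, record=())
    RA, RB = np.meshgrid(apical_rates, basal_rates, indexing="ij")
    B = RA.size
    sources = []
    for comp in apical_comps:
        sources.append(PoissonInput(comp, ReceptorSpec("AMPA_NMDA", 0.2, 3.0,
                                                       0.0, weight), RA.ravel()))
        sources.append(PoissonInput(comp, ReceptorSpec("GABA", 0.2, 10.0,
                                                       -80.0, weight), gaba_rate))
    for comp in basal_comps:
        sources.append(PoissonInput(comp, ReceptorSpec("AMPA_NMDA", 0.2, 3.0,
                                                       0.0, weight), RB.ravel()))
        sources.append(PoissonInput(comp, ReceptorSpec("GABA", 0.2, 10.0,
                                                       -80.0, weight), gaba_rate))
    N = tree.n
    rates = np.zeros((episodes,) + RA.shape)
    mean_v = np.zeros((episodes, N) + RA.shape)
    for ep in range(episodes):
        cfg = SolverConfig(h=config.h, T=episode_ms, record=())
        eng = Engine(tree, cfg, B=B, sources=sources,
                     seed=None if seed is None else seed + ep)
        vsum = np.zeros((N, B))
        nacc = 0

        def acc(engine, k, spiking):
            nonlocal nacc
            vsum[...] += engine.V
            nacc += 1

        eng.on_step = acc
        eng.run()
        rates[ep] = eng.spike_counts().reshape(RA.shape) / (episode_ms * 1e-3)
        mean_v[ep] = (vsum / nacc).reshape((N,) + RA.shape)
    return {
        "apical_rates": apical_rates,
        "basal_rates": basal_rates,
        "rate": rates.mean(axis=0),
        "mean_voltage": mean_v.mean(axis=0),   # (N, nA, nB)
    }
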