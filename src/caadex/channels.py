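"""Current laws and state updates: Ca-HZ channels, AdEx terms, synapses.

All functions are pure and accept numpy arrays or scalars; voltages in mV,
conductances in nS, currents in pA, concentrations in mM, times in ms.
Currents follow the driving-force sign convention ``I = g (E - V)``
(positive = depolarizing), so they add directly to the membrane equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ConfigurationError

__all__ = [
    "EXP_ARG_CLAMP",
    "sigmoid_inf",
    "ca_m_inf", "ca_h_inf", "kca_m_inf",
    "ca_hva_current", "kca_current",
    "update_calcium", "gating_step",
    "adex_exponential_current", "adex_terms",
    "ReceptorSpec", "double_exp_normalization", "double_exp_peak_time",
    "receptor_conductance", "nmda_block",
]

#: Clamp on the argument of the AdEx exponential (numerical safety only;
#: spikes are detected at V_th well before the clamp matters).
EXP_ARG_CLAMP = 10.0


def sigmoid_inf(V, slope, half):
    """Steady-state sigmoid ``1/(1+exp(slope (V - half)))``.

    A negative ``slope`` gives a curve increasing with V (activation).
    """
    return 1.0 / (1.0 + np.exp(np.clip(slope * (np.asarray(V, float) - half), -60.0, 60.0)))


def ca_m_inf(V, spec):
    return sigmoid_inf(V, spec.m_slope, spec.m_half)


def ca_h_inf(V, spec):
    return sigmoid_inf(V, spec.h_slope, spec.h_half)


def kca_m_inf(Ca, spec):
    """Calcium-dependent K_Ca activation, ``1/(1+(Ca_th/Ca)**const_KCa)``.

    At ``Ca = 0`` the continuous limit 0 is returned (fully closed).
    """
    Ca = np.asarray(Ca, float)
    out = np.zeros_like(Ca)
    pos = Ca > 0
    ratio = np.where(pos, spec.Ca_th / np.where(pos, Ca, 1.0), np.inf)
    out = np.where(pos, 1.0 / (1.0 + ratio ** spec.const_KCa), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def ca_hva_current(m, h, V, spec):
    """High-voltage-activated calcium current ``g_Ca m h (E_Ca - V)`` (pA)."""
    return spec.g_Ca * m * h * (spec.E_Ca - V)


def kca_current(m, V, spec):
    """Ca-activated potassium current ``g_K m (E_K - V)`` (pA)."""
    return spec.g_K * m * (spec.E_K - V)


def update_calcium(Ca, I_Ca, h, spec):
    """One exponential-integration step of the calcium pool.

    ``d[Ca]/dt = phi_Ca I_Ca - ([Ca]-Ca_0)/tau_Ca`` with ``I_Ca`` held
    constant over the step has the exact solution
    ``Ca' = Ca_ss + (Ca - Ca_ss) exp(-h/tau_Ca)`` where
    ``Ca_ss = Ca_0 + phi_Ca I_Ca tau_Ca``.
    """
    Ca_ss = spec.Ca_0 + spec.phi_Ca * I_Ca * spec.tau_Ca
    P = math.exp(-h / spec.tau_Ca)
    return Ca_ss + (Ca - Ca_ss) * P


def gating_step(y, y_inf, tau, h):
    """Exponential-propagator update of a first-order gating variable.

    ``y' = P y + (1-P) y_inf`` with ``P = exp(-h/tau)`` — the exact
    solution of ``dy/dt = (y_inf - y)/tau`` over a step during which the
    steady state (i.e. the voltage) is held constant.
    """
    P = np.exp(-h / np.asarray(tau, float))
    return P * y + (1.0 - P) * y_inf


def adex_exponential_current(V, g_L, Delta_T, V_th_s):
    """AdEx spike-initiation current ``g_L Delta_T exp((V-V_th_s)/Delta_T)``.

    The exponent argument is clamped at :data:`EXP_ARG_CLAMP` so runaway
    voltages cannot overflow; spike detection happens at ``V_th`` anyway.
    """
    arg = np.minimum((np.asarray(V, float) - V_th_s) / Delta_T, EXP_ARG_CLAMP)
    return g_L * Delta_T * np.exp(arg)


def adex_terms(V_s, w, mech, g_L_s):
    """Net AdEx contribution: exponential current minus adaptation ``g_w w``."""
    return adex_exponential_current(V_s, g_L_s, mech.Delta_T, mech.V_th_s) - mech.g_w * w


# ---------------------------------------------------------------------------
# Synaptic receptors

RECEPTOR_KINDS = ("AMPA", "GABA", "NMDA", "AMPA_NMDA", "BETA_CURRENT")

#: Conventional kinetics (ms) and reversals (mV) per receptor kind.
RECEPTOR_DEFAULTS = {
    "AMPA": dict(tau_r=0.2, tau_d=3.0, e_r=0.0),
    "GABA": dict(tau_r=0.2, tau_d=10.0, e_r=-80.0),
    "NMDA": dict(tau_r=0.2, tau_d=43.0, e_r=0.0),
}


@dataclass
class ReceptorSpec:
    """A synaptic receptor (or beta-shaped current source) on a compartment.

    The conductance (or, for ``BETA_CURRENT``, the injected current) of one
    presynaptic spike is the normalized double exponential
    ``w n (exp(-t/tau_d) - exp(-t/tau_r))`` whose peak equals ``w`` exactly.
    ``AMPA_NMDA`` is an AMPA window plus an NMDA window (peak
    ``nmda_ratio * w``, default 2) sharing the same spike train; the NMDA
    component is multiplied by the magnesium-block factor
    :func:`nmda_block`.
    """

    kind: str
    tau_r: float            # rise, ms
    tau_d: float            # decay, ms
    e_r: float = 0.0        # reversal, mV (unused for BETA_CURRENT)
    w: float = 1.0          # peak conductance nS (peak current pA for BETA_CURRENT)
    nmda_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in RECEPTOR_KINDS:
            raise ConfigurationError(f"unknown receptor kind '{self.kind}'")
        if not (self.tau_d > self.tau_r > 0):
            raise ConfigurationError(
                f"receptor requires tau_d > tau_r > 0 (got tau_r={self.tau_r}, tau_d={self.tau_d})"
            )
        if self.w < 0:
            raise ConfigurationError("receptor weight w must be >= 0")


def double_exp_peak_time(tau_r: float, tau_d: float) -> float:
    """Time of the single interior maximum of the double-exponential window."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def double_exp_normalization(tau_r: float, tau_d: float) -> float:
    """Factor n(tau_r, tau_d) making the window peak equal 1."""
    t_peak = double_exp_peak_time(tau_r, tau_d)
    return 1.0 / (math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r))


def receptor_conductance(spec: ReceptorSpec, spike_times, t):
    """Summed double-exponential windows of past spikes, evaluated at ``t``.

    Returns conductance in nS (current in pA for ``BETA_CURRENT``).  Each
    window is zero before its spike and peaks at exactly ``spec.w``.
    """
    n = double_exp_normalization(spec.tau_r, spec.tau_d)
    t = np.asarray(t, float)
    total = np.zeros_like(t)
    for ts in np.atleast_1d(spike_times):
        dt = t - ts
        active = dt >= 0
        dtp = np.where(active, dt, 0.0)
        total = total + np.where(
            active,
            spec.w * n * (np.exp(-dtp / spec.tau_d) - np.exp(-dtp / spec.tau_r)),
            0.0,
        )
    if total.ndim == 0:
        return float(total)
    return total


def nmda_block(V):
    """NMDA magnesium-block factor ``sigma(V) = 1/(1 + 0.3 exp(-0.1 V))``.

    Strictly increasing in V, in (0, 1); the NMDA current is
    ``g sigma(V) (e_r - V)``.
    """
    return 1.0 / (1.0 + 0.3 * np.exp(-0.1 * np.asarray(V, float)))
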