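"""Brain-state modulation proxies: apical-amplification, -isolation, -drive.

Neuromodulation (cholinergic/noradrenergic) is emulated by three genome
transforms: changing the spike-frequency-adaptation increment ``b``,
shifting the somatic and distal leak reversal potentials, and (for
isolation) zeroing the coupling conductance ``g_C`` so the soma ignores
the apical compartment entirely.  The named presets:

* AA (wakefulness): the fitted genome itself; ``b`` may be retuned.
* AI (deep NREM sleep / anesthesia): b = 200, g_C = 0, both leak
  reversals lowered by 5 mV; optionally the somatic block is replaced by
  the reference single-compartment AdEx parameters, which makes the
  somatic spike train exactly equal to the pure AdEx one for any distal
  input (with g_C = 0 the somatic equation decouples).
* AD (REM sleep / dreaming): b = 10, both leak reversals lowered by 2 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import Genome

__all__ = ["BrainStatePreset", "PRESETS", "apply_brain_state"]


@dataclass
class BrainStatePreset:
    name: str
    b_value: Optional[float] = None         # None = keep the genome's b
    delta_E_L: float = 0.0                  # mV, applied to E_L_s and E_L_d
    g_C_override: Optional[float] = None
    soma_params_override: dict = field(default_factory=dict)


PRESETS = {
    "AA": BrainStatePreset(name="AA"),
    "AI": BrainStatePreset(name="AI", b_value=200.0, delta_E_L=-5.0,
                           g_C_override=0.0),
    "AD": BrainStatePreset(name="AD", b_value=10.0, delta_E_L=-2.0),
}


def apply_brain_state(genome: Genome, preset) -> Genome:
    """Return a transformed copy of the genome; the original is untouched.

    ``preset`` is a :class:`BrainStatePreset` or one of the names
    "AA", "AI", "AD".  Applying AA with ``b_value`` equal to the genome's
    own ``b`` is the identity transform.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown brain-state preset '{preset}'") from None
    updates = {}
    if preset.b_value is not None:
        updates["b"] = preset.b_value
    if preset.delta_E_L:
        updates["E_L_s"] = genome["E_L_s"] + preset.delta_E_L
        updates["E_L_d"] = genome["E_L_d"] + preset.delta_E_L
    if preset.g_C_override is not None:
        updates["g_C"] = preset.g_C_override
    updates.update(preset.soma_params_override)
    return genome.replace(**updates) if updates else genome.replace()
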