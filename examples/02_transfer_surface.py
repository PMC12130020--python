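"""Transfer surface nu(I_s, I_d) and its ThetaPlanes approximation.

Scans DC current pairs, locates the distal-only calcium-activation jump,
fits the two planes plus boundary/rheobase lines, and prints the fit
errors per region (Hz).
"""
import numpy as np

from caadex import build_two_compartment, reference_genome
from caadex.protocols import run_prolonged_scan
from caadex.thetaplanes import fit_report, fit_thetaplanes

tree = build_two_compartment(reference_genome())
surf = run_prolonged_scan(tree, np.arange(0.0, 601.0, 50.0),
                          np.arange(0.0, 1001.0, 50.0), stim_ms=2000.0)
print(f"rate range: {surf.rate.min():.1f} .. {surf.rate.max():.1f} Hz")

row = run_prolonged_scan(tree, [0.0], np.arange(0.0, 1001.0, 10.0),
                         stim_ms=2000.0)
jump = row.Id_grid[np.argmax(row.ca_active[0])]
print(f"distal-only Ca-activation jump at I_d = {jump:.0f} pA")

model = fit_thetaplanes(surf, nu_low=10.0, I_th=500.0)
print(f"high-rate plane: nu+ = {model.a_plus:.4f} I_s + {model.b_plus:.4f} I_d "
      f"+ {model.d_plus:.2f}")
print(f"boundary line:   I_d = {model.theta_m_H:.3f} I_s + {model.theta_q_H:.0f}")
rep = fit_report(surf, model)
for region, r in rep.items():
    print(f"  {region}: n={r['n']} RMS={r['rms_err']:.2f} Hz "
          f"max={r['max_abs_err']:.2f} Hz")
print("The two planes + two lines compress the whole spiking surface into")
print("ten numbers usable as a transfer function in abstract networks.")
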