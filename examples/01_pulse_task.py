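"""BAC firing: the four-case pulse task on the fitted reference neuron.

A subthreshold EPSP-shaped current into the apical compartment (A) barely
deflects the soma; a brief somatic pulse (B) gives one spike; their
coincidence (C) ignites the dendritic calcium spike and a three-spike
burst; a much stronger apical input (D) is needed to burst on its own.
"""
from caadex import PulseTaskSpec, build_two_compartment, reference_genome
from caadex.protocols import run_pulse_task, find_burst_threshold

tree = build_two_compartment(reference_genome())
spec = PulseTaskSpec()
report = run_pulse_task(tree, spec)
for name, case in report.cases.items():
    print(f"case {name}: {case.spike_count} spike(s), "
          f"somatic deflection {case.somatic_deflection:.1f} mV, "
          f"burst={case.is_burst}")
thr = find_burst_threshold(tree, spec)
print(f"minimal distal-only beta peak evoking a burst: {thr:.0f} pA")
print("Coincidence of a weak apical and a threshold somatic input thus")
print("produces a burst that neither input evokes alone.")
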