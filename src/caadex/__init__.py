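"""caadex: two-compartment Ca-AdEx spiking neuron with dendritic calcium.

A somatic adaptive exponential integrate-and-fire compartment coupled to
an apical "calcium hot zone" reproduces BAC firing, brain-state-specific
apical amplification / isolation / drive, and a transfer surface
nu(I_s, I_d) that a piecewise-planar ThetaPlanes function approximates.
The package also ships the fitness-function suite and genetic algorithm
used to fit the model, plus a balanced-network benchmark.
"""

from importlib import resources as _resources

__version__ = "0.1.0"

from .model import (                                    # noqa: F401
    AdExMechanism, CaHotzoneMechanism, Compartment, CompartmentTree,
    Genome, GENOME_PARAMETERS, DEFAULT_BOUNDS,
    build_tree, build_two_compartment, validate_genome,
)
from .channels import ReceptorSpec, nmda_block          # noqa: F401
from .solver import (                                   # noqa: F401
    SolverConfig, SimulationResult, StepCurrent, BetaCurrent,
    SpikeTrainInput, PoissonInput, simulate, hines_solve, Engine,
)
from .protocols import (                                # noqa: F401
    PulseTaskSpec, TransferSurface, run_pulse_task, find_burst_threshold,
    run_prolonged_scan, detect_ca_activation, spike_stats, run_poisson_scan,
)
from .thetaplanes import (                              # noqa: F401
    ThetaPlanesModel, compute_masks, fit_planes, fit_boundary_and_rheobase,
    fit_thetaplanes, evaluate, fit_report,
)
from .fitness import (                                  # noqa: F401
    FitnessReport, FitnessProtocol, emd_1d, evaluate_genome,
)
from .evolution import run_ga, convergence_stats, GAConfig  # noqa: F401
from .modulation import BrainStatePreset, PRESETS, apply_brain_state  # noqa: F401
from .network import (                                  # noqa: F401
    NetworkSpec, build_brunel_network, simulate_network, calibrate_network_rate,
)


def reference_genome() -> "Genome":
    """The fitted reference Ca-AdEx genome shipped with the package.

    Produced by the package's own evolutionary/local fitting machinery so
    that the pulse task, the 550 pA distal activation jump and the
    brain-state rate ranges come out as documented (see docs/methods.md).
    """
    from .io import read_genome
    with _resources.as_file(
            _resources.files("caadex").joinpath("data/reference_genome.json")) as p:
        return read_genome(p)


def target_adex_parameters() -> dict:
    """Parameters of the reference single-compartment AdEx (soma target)."""
    import json
    return json.loads(_resources.files("caadex")
                      .joinpath("data/target_adex.json").read_text())
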