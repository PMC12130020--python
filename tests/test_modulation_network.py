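"""Brain-state presets and the balanced-network benchmark."""

import numpy as np
import pytest

from caadex.model import AdExMechanism, Compartment, build_tree, build_two_compartment
from caadex.modulation import PRESETS, apply_brain_state
from caadex.network import (
    NetworkSpec,
    build_brunel_network,
    simulate_network,
)
from caadex.solver import SolverConfig, StepCurrent, simulate


class TestPresets:
    def test_ai_changes_exactly_the_documented_parameters(self, ref_genome):
        g = apply_brain_state(ref_genome, "AI")
        diffs = {k for k in ref_genome.values
                 if g.values[k] != ref_genome.values[k]}
        assert diffs == {"b", "g_C", "E_L_s", "E_L_d"}
        assert g["b"] == 200.0 and g["g_C"] == 0.0
        assert g["E_L_s"] == ref_genome["E_L_s"] - 5.0
        assert g["E_L_d"] == ref_genome["E_L_d"] - 5.0

    def test_ad_preset_values(self, ref_genome):
        g = apply_brain_state(ref_genome, "AD")
        assert g["b"] == 10.0
        assert g["E_L_s"] == ref_genome["E_L_s"] - 2.0
        assert g["g_C"] == ref_genome["g_C"]

    def test_aa_with_own_b_is_identity(self, ref_genome):
        from caadex.modulation import BrainStatePreset
        preset = BrainStatePreset(name="AA", b_value=ref_genome["b"])
        g = apply_brain_state(ref_genome, preset)
        assert g.values == ref_genome.values

    def test_original_untouched(self, ref_genome):
        before = dict(ref_genome.values)
        apply_brain_state(ref_genome, "AI")
        assert ref_genome.values == before

    def test_unknown_preset_rejected(self, ref_genome):
        with pytest.raises(ValueError):
            apply_brain_state(ref_genome, "REM")

    def test_ai_with_soma_override_reduces_to_pure_adex(self, ref_genome):
        """g_C = 0 + target-AdEx soma: somatic train equals the pure AdEx one
        for any distal input."""
        from caadex import target_adex_parameters
        from caadex.modulation import BrainStatePreset
        tgt = target_adex_parameters()
        override = {k: tgt[k] for k in ("C_m_s", "g_L_s", "E_L_s", "Delta_T",
                                        "V_th_s", "V_th", "V_reset", "t_ref",
                                        "a", "b", "tau_w")}
        preset = BrainStatePreset(name="AI", b_value=None, g_C_override=0.0,
                                  soma_params_override=override)
        g = apply_brain_state(ref_genome, preset)
        tree2 = build_two_compartment(g)
        soma = Compartment(id=0, parent=None, C_m=tgt["C_m_s"], g_L=tgt["g_L_s"],
                           E_L=tgt["E_L_s"],
                           channels=[AdExMechanism(
                               Delta_T=tgt["Delta_T"], V_th_s=tgt["V_th_s"],
                               V_th=tgt["V_th"], V_reset=tgt["V_reset"],
                               t_ref=tgt["t_ref"], a=tgt["a"], b=tgt["b"],
                               tau_w=tgt["tau_w"], w_BAP=g["w_BAP"],
                               d_BAP=g["d_BAP"])])
        tree1 = build_tree([soma])
        cfg = SolverConfig(h=0.1, T=1000.0, record=("V",))
        r2 = simulate(tree2, [StepCurrent(0, 700.0), StepCurrent(1, 900.0)], cfg)
        r1 = simulate(tree1, [StepCurrent(0, 700.0)], cfg)
        assert r2.spike_times == r1.spike_times


class TestWiring:
    def test_fixed_in_degree_and_no_self_connections(self, ref_genome):
        spec = NetworkSpec(N_exc=40, N_inh=10, K=25, duration=100.0, seed=3)
        net = build_brunel_network(spec, ref_genome)
        assert net.sources_exc.shape == (50, 20)
        assert net.sources_inh.shape == (50, 5)
        for i in range(50):
            assert i not in net.sources_exc[i]
            assert i not in net.sources_inh[i]
            assert len(set(net.sources_exc[i])) == 20
            assert np.all(net.sources_exc[i] < 40)
            assert np.all(net.sources_inh[i] >= 40)

    def test_wiring_reproducible_per_seed(self, ref_genome):
        spec = NetworkSpec(N_exc=40, N_inh=10, K=25, seed=11)
        n1 = build_brunel_network(spec, ref_genome)
        n2 = build_brunel_network(spec, ref_genome)
        assert np.array_equal(n1.sources_exc, n2.sources_exc)
        assert np.array_equal(n1.sources_inh, n2.sources_inh)

    def test_infeasible_k_rejected(self, ref_genome):
        with pytest.raises(ValueError):
            build_brunel_network(NetworkSpec(N_exc=40, N_inh=10, K=50), ref_genome)

    def test_k_not_divisible_by_five_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(N_exc=40, N_inh=10, K=23)


class TestNetworkSimulation:
    def test_silent_without_drive(self, ref_genome):
        spec = NetworkSpec(N_exc=40, N_inh=10, K=25, J_exc=0.0,
                           noise_rate=0.0, noise_weight=0.0, duration=200.0)
        net = build_brunel_network(spec, ref_genome)
        res = simulate_network(net)
        assert res["mean_rate"] == 0.0

    def test_driven_network_fires_and_reports(self, ref_genome):
        spec = NetworkSpec(N_exc=40, N_inh=10, K=25, J_exc=0.05,
                           noise_rate=30000.0, noise_weight=0.15,
                           duration=500.0, seed=0)
        net = build_brunel_network(spec, ref_genome)
        res = simulate_network(net)
        assert res["mean_rate"] > 0
        assert res["spikes"].shape[1] == 2
        assert np.all(np.diff(res["spikes"][:, 0]) >= 0)

    def test_simulation_reproducible_per_seed(self, ref_genome):
        spec = NetworkSpec(N_exc=40, N_inh=10, K=25, J_exc=0.05,
                           noise_rate=30000.0, noise_weight=0.03,
                           duration=300.0, seed=4)
        net = build_brunel_network(spec, ref_genome)
        r1 = simulate_network(net, seed=9)
        r2 = simulate_network(net, seed=9)
        assert np.array_equal(r1["spikes"], r2["spikes"])
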