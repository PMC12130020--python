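"""Crank-Nicolson/Hines integrator: oracles, convergence, spike handling."""

import numpy as np
import pytest
from scipy.linalg import expm

from caadex.model import AdExMechanism, Compartment, build_tree
from caadex.solver import (
    Engine,
    NumericalError,
    SolverConfig,
    StepCurrent,
    dense_from_tree_system,
    hines_solve,
    simulate,
)
from caadex.fixtures import passive_tree


def _adex(**kw):
    base = dict(Delta_T=2.0, V_th_s=-50.0, V_th=-30.0, V_reset=-60.0,
                t_ref=2.0, a=4.0, b=60.0, tau_w=100.0)
    base.update(kw)
    return AdExMechanism(**base)


class TestHinesSolve:
    def test_single_compartment_is_scalar_division(self):
        x = hines_solve(np.array([0]), np.array([4.0]), np.array([0.0]),
                        np.array([8.0]))
        assert x[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_solve_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        parent = np.array([0] + [int(rng.integers(0, i)) for i in range(1, n)])
        off = -rng.uniform(0.5, 2.0, n)
        off[0] = 0.0
        diag = rng.uniform(5.0, 10.0, n)    # diagonally dominant
        rhs = rng.normal(size=n)
        x = hines_solve(parent, diag, off, rhs)
        A = dense_from_tree_system(parent, diag, off)
        x_dense = np.linalg.solve(A, rhs)
        assert np.max(np.abs(x - x_dense)) / np.max(np.abs(x_dense)) < 1e-12

    def test_zero_couplings_decouple(self):
        parent = np.array([0, 0, 1])
        diag = np.array([2.0, 4.0, 8.0])
        rhs = np.array([2.0, 8.0, 16.0])
        x = hines_solve(parent, diag, np.zeros(3), rhs)
        assert np.allclose(x, [1.0, 2.0, 2.0])

    def test_singular_diagonal_reports_compartment(self):
        with pytest.raises(NumericalError, match="compartment"):
            hines_solve(np.array([0, 0]), np.array([1.0, 0.0]),
                        np.array([0.0, -1.0]), np.array([1.0, 1.0]))

    def test_batched_agrees_with_loop(self):
        rng = np.random.default_rng(3)
        parent = np.array([0, 0, 1, 2])
        diag = rng.uniform(5, 9, (7, 4))
        off = -rng.uniform(0.2, 1.0, (7, 4))
        off[:, 0] = 0
        rhs = rng.normal(size=(7, 4))
        batch = hines_solve(parent, diag, off, rhs)
        for b in range(7):
            single = hines_solve(parent, diag[b], off[b], rhs[b])
            assert np.array_equal(batch[b], single)


class TestPassiveDynamics:
    def test_single_compartment_step_response(self):
        tree = build_tree([Compartment(id=0, parent=None, C_m=200.0, g_L=10.0,
                                       E_L=-70.0)])
        cfg = SolverConfig(h=0.1, T=100.0)
        res = simulate(tree, [StepCurrent(0, 100.0)], cfg)
        tau = 20.0
        exact = -70.0 + 10.0 * (1.0 - np.exp(-res.times / tau))
        assert np.max(np.abs(res.voltages[:, 0] - exact)) < 1e-4

    def test_two_compartment_matches_matrix_exponential(self):
        c0 = Compartment(id=0, parent=None, C_m=200.0, g_L=10.0, E_L=-70.0)
        c1 = Compartment(id=1, parent=0, C_m=100.0, g_L=5.0, E_L=-70.0, g_C=8.0)
        tree = build_tree([c0, c1])
        res = simulate(tree, [StepCurrent(1, 200.0)], SolverConfig(h=0.1, T=100.0))
        A = np.array([[-(10 + 8) / 200, 8 / 200], [8 / 100, -(5 + 8) / 100]])
        b = np.array([10 * -70.0 / 200, (5 * -70.0 + 200.0) / 100])
        x_inf = -np.linalg.solve(A, b)
        x0 = np.array([-70.0, -70.0])
        for k in (100, 500, 999):
            t = res.times[k]
            exact = expm(A * t) @ (x0 - x_inf) + x_inf
            assert np.max(np.abs(res.voltages[k] - exact)) < 2e-4

    def test_rest_is_equilibrium(self):
        tree = passive_tree(n=4, seed=5)
        res = simulate(tree, [], SolverConfig(h=0.1, T=50.0))
        assert np.max(np.abs(res.voltages + 70.0)) < 1e-10

    def test_relaxation_is_monotone(self):
        """With equal E_L everywhere, total deviation decays monotonically."""
        tree = passive_tree(n=3, seed=2)
        res = simulate(tree, [StepCurrent(2, 300.0, 0.0, 20.0)],
                       SolverConfig(h=0.1, T=120.0))
        dev = np.sum(np.abs(res.voltages + 70.0), axis=1)
        after = dev[220:]
        assert np.all(np.diff(after) <= 1e-9)

    def test_order_two_convergence(self):
        """Halving h reduces the passive-trajectory error ~4x (slope ~2)."""
        c0 = Compartment(id=0, parent=None, C_m=150.0, g_L=12.0, E_L=-70.0)
        c1 = Compartment(id=1, parent=0, C_m=80.0, g_L=6.0, E_L=-70.0, g_C=10.0)
        tree = build_tree([c0, c1])
        A = np.array([[-(12 + 10) / 150, 10 / 150], [10 / 80, -(6 + 10) / 80]])
        b = np.array([12 * -70.0 / 150 + 150.0 / 150, (6 * -70.0 + 250.0) / 80])
        x_inf = -np.linalg.solve(A, b)
        x0 = np.array([-70.0, -70.0])
        T = 40.0
        exact = expm(A * T) @ (x0 - x_inf) + x_inf
        errs, hs = [], [0.4, 0.2, 0.1, 0.05]
        for h in hs:
            res = simulate(tree, [StepCurrent(0, 150.0), StepCurrent(1, 250.0)],
                           SolverConfig(h=h, T=T))
            errs.append(np.max(np.abs(res.voltages[-1] - exact)))
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 1.8 <= slope <= 2.2


class TestSpikingContracts:
    def _soma_tree(self, **kw):
        soma = Compartment(id=0, parent=None, C_m=200.0, g_L=10.0, E_L=-70.0,
                           channels=[_adex(**kw)])
        return build_tree([soma])

    def test_refractory_spacing_and_clamp(self):
        tree = self._soma_tree(t_ref=3.0)
        res = simulate(tree, [StepCurrent(0, 600.0)], SolverConfig(h=0.1, T=500.0))
        st = np.asarray(res.spike_times)
        assert len(st) > 3
        assert np.all(np.diff(st) >= 3.0 - 1e-9)
        # V_s equals V_reset throughout each refractory window
        for t_k in st[:-1]:
            i0 = int(round(t_k / 0.1))
            window = res.voltages[i0 + 1:i0 + 30, 0]
            assert np.all(window == -60.0)

    def test_same_config_is_bit_identical(self, ref_tree):
        cfg = SolverConfig(h=0.1, T=300.0)
        r1 = simulate(ref_tree, [StepCurrent(0, 500.0)], cfg, seed=7)
        r2 = simulate(ref_tree, [StepCurrent(0, 500.0)], cfg, seed=7)
        assert np.array_equal(r1.voltages, r2.voltages)
        assert r1.spike_times == r2.spike_times

    def test_bap_event_per_spike_with_delay(self, ref_genome):
        from caadex.model import build_two_compartment
        tree = build_two_compartment(ref_genome)
        d_bap = ref_genome["d_BAP"]
        res = simulate(tree, [StepCurrent(0, 800.0)], SolverConfig(h=0.1, T=400.0))
        assert len(res.spike_times) > 0
        baps = [e for e in res.events_delivered if e[0] == "BAP"]
        # one delivery per spike whose delay fits inside the simulated window
        due = [t for t in res.spike_times if t + d_bap <= 400.0]
        assert len(baps) == len(due)
        for (_, t_bap, _), t_spike in zip(baps, due):
            assert t_bap == pytest.approx(t_spike + d_bap, abs=0.051)

    def test_bap_charge_independent_of_h(self, ref_genome):
        """Distal calcium response to one BAP is step-size invariant."""
        from caadex.model import build_two_compartment
        tree = build_two_compartment(ref_genome)
        peaks = []
        for h in (0.1, 0.05):
            res = simulate(tree, [StepCurrent(0, 1150.0, 20.0, 25.0)],
                           SolverConfig(h=h, T=60.0))
            assert len(res.spike_times) == 1
            peaks.append(res.v_max[1])
        assert peaks[0] == pytest.approx(peaks[1], abs=1.0)

    def test_gc_zero_reduces_to_single_compartment(self, ref_genome):
        """With g_C = 0 the somatic spike train is exactly the pure AdEx one."""
        from caadex.model import build_two_compartment
        g0 = ref_genome.replace(g_C=0.0)
        tree2 = build_two_compartment(g0)
        soma = Compartment(id=0, parent=None, C_m=g0["C_m_s"], g_L=g0["g_L_s"],
                           E_L=g0["E_L_s"],
                           channels=[AdExMechanism(
                               Delta_T=g0["Delta_T"], V_th_s=g0["V_th_s"],
                               V_th=g0["V_th"], V_reset=g0["V_reset"],
                               t_ref=g0["t_ref"], a=g0["a"], b=g0["b"],
                               tau_w=g0["tau_w"], g_w=g0["g_w"],
                               w_BAP=g0["w_BAP"], d_BAP=g0["d_BAP"])])
        tree1 = build_tree([soma])
        cfg = SolverConfig(h=0.1, T=1500.0, record=("V",))
        # distal stimulus present in the 2-compartment run only
        r2 = simulate(tree2, [StepCurrent(0, 520.0), StepCurrent(1, 700.0)], cfg)
        r1 = simulate(tree1, [StepCurrent(0, 520.0)], cfg)
        assert r2.spike_times == r1.spike_times
        assert np.array_equal(r2.voltages[:, 0], r1.voltages[:, 0])

    def test_nonfinite_voltage_is_reported(self):
        soma = Compartment(id=0, parent=None, C_m=1e-3, g_L=0.0, E_L=-70.0)
        tree = build_tree([soma])
        with pytest.raises(NumericalError, match="compartment"):
            simulate(tree, [StepCurrent(0, 1e308)], SolverConfig(h=0.1, T=10.0))


class TestBetweenSpikeAccuracy:
    def test_full_model_matches_fine_step_between_spikes(self, ref_genome):
        """Subthreshold Ca-AdEx trajectory vs an h/20 reference run."""
        from caadex.model import build_two_compartment
        tree = build_two_compartment(ref_genome)
        prog = [StepCurrent(0, 120.0), StepCurrent(1, 150.0)]
        coarse = simulate(tree, prog, SolverConfig(h=0.1, T=200.0))
        fine = simulate(tree, prog, SolverConfig(h=0.005, T=200.0))
        assert len(coarse.spike_times) == 0
        sel = np.arange(0, 40001, 20)
        dv = np.abs(coarse.voltages[:, 0] - fine.voltages[sel][:, 0])
        assert dv.max() < 0.1
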