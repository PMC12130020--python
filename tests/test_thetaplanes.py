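"""Piecewise-planar transfer-function fitting and evaluation."""

import numpy as np
import pytest

from caadex.protocols import TransferSurface
from caadex.thetaplanes import (
    FitError,
    ThetaPlanesModel,
    compute_masks,
    evaluate,
    fit_boundary_and_rheobase,
    fit_planes,
    fit_report,
    fit_thetaplanes,
)
from caadex.fixtures import planar_surface


def _surface(rate, active, Is, Id):
    return TransferSurface(Is_grid=Is, Id_grid=Id, rate=rate, ca_active=active)


def _grids(step=50.0):
    Is = np.arange(0.0, 601.0, step)
    Id = np.arange(0.0, 1001.0, step)
    return Is, Id, np.meshgrid(Is, Id, indexing="ij")


class TestMasks:
    def test_all_silent_surface_gives_empty_masks(self):
        Is, Id, (II_s, II_d) = _grids()
        surf = _surface(np.zeros(II_s.shape), np.zeros(II_s.shape, bool), Is, Id)
        M_plus, M_minus = compute_masks(surf)
        assert not M_plus.any() and not M_minus.any()

    def test_exclusion_band_removes_high_Is(self):
        Is, Id, (II_s, II_d) = _grids()
        rate = np.full(II_s.shape, 50.0)
        act = np.ones(II_s.shape, bool)
        M_plus, M_minus = compute_masks(_surface(rate, act, Is, Id), I_th=300.0)
        assert not M_plus[Is > 300.0].any()
        act[:] = False
        M_plus, M_minus = compute_masks(_surface(rate, act, Is, Id), I_th=300.0)
        assert not M_minus[Is > 300.0].any()

    def test_boundary_recovered_within_one_cell(self):
        surf, model = planar_surface(step=25.0)
        M_plus, _ = compute_masks(surf, nu_low=model.nu_low)
        for i, Is in enumerate(surf.Is_grid):
            idx = np.flatnonzero(M_plus[i])
            if idx.size:
                true_b = model.theta_m_H * Is + model.theta_q_H
                assert abs(surf.Id_grid[idx[0]] - true_b) <= 25.0


class TestFitPlanes:
    def test_exact_recovery(self):
        Is, Id, (II_s, II_d) = _grids()
        rate = 0.05 * II_s + 0.08 * II_d + 3.0
        mask = np.ones(II_s.shape, bool)
        (a, b, d), rep = fit_planes(_surface(rate, mask, Is, Id), mask)
        assert a == pytest.approx(0.05, abs=1e-10)
        assert b == pytest.approx(0.08, abs=1e-10)
        assert d == pytest.approx(3.0, abs=1e-8)
        assert rep["max_abs_err"] < 1e-9

    def test_constant_surface(self):
        Is, Id, (II_s, II_d) = _grids()
        mask = np.ones(II_s.shape, bool)
        (a, b, d), _ = fit_planes(_surface(np.full(II_s.shape, 7.0), mask, Is, Id),
                                  mask)
        assert (a, b) == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))
        assert d == pytest.approx(7.0)

    def test_noisy_recovery_within_three_standard_errors(self):
        """Monte-Carlo over seeds: OLS coefficients stay near truth."""
        Is, Id, (II_s, II_d) = _grids()
        mask = np.ones(II_s.shape, bool)
        sigma = 0.5
        X = np.column_stack([II_s.ravel(), II_d.ravel()])
        Xc = np.column_stack([np.ones(len(X)), X])
        cov = sigma ** 2 * np.linalg.inv(Xc.T @ Xc)
        se_a, se_b = np.sqrt(cov[1, 1]), np.sqrt(cov[2, 2])
        misses = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rate = 0.05 * II_s + 0.08 * II_d + 3.0 + rng.normal(0, sigma, II_s.shape)
            (a, b, _), _ = fit_planes(_surface(np.maximum(rate, 0), mask, Is, Id),
                                      mask)
            if abs(a - 0.05) > 3 * se_a or abs(b - 0.08) > 3 * se_b:
                misses += 1
        assert misses <= 5     # ~0.3% expected per coefficient

    def test_degenerate_mask_raises(self):
        Is, Id, (II_s, II_d) = _grids()
        mask = np.zeros(II_s.shape, bool)
        mask[0, :3] = True      # collinear points
        with pytest.raises(FitError):
            fit_planes(_surface(II_s * 0.1, mask, Is, Id), mask)


class TestBoundaryAndRheobase:
    def test_synthetic_boundary_line(self):
        surf, model = planar_surface(step=10.0)
        masks = compute_masks(surf, nu_low=model.nu_low)
        minus = (model.a_minus, model.b_minus, model.d_minus)
        lines = fit_boundary_and_rheobase(surf, masks, minus)
        assert lines["theta_m_H"] == pytest.approx(-0.5, abs=0.05)
        assert lines["theta_q_H"] == pytest.approx(600.0, abs=10.0)

    def test_rheobase_is_zero_locus_of_low_plane(self):
        surf, model = planar_surface()
        masks = compute_masks(surf, nu_low=model.nu_low)
        lines = fit_boundary_and_rheobase(surf, masks, (0.0, 0.1, -10.0))
        assert lines["theta_m_rho"] == pytest.approx(0.0)
        assert lines["theta_q_rho"] == pytest.approx(100.0)

    def test_flat_low_plane_rejected(self):
        surf, model = planar_surface()
        masks = compute_masks(surf, nu_low=model.nu_low)
        with pytest.raises(FitError):
            fit_boundary_and_rheobase(surf, masks, (0.1, 0.0, -10.0))


class TestEvaluate:
    @pytest.fixture()
    def model(self):
        return ThetaPlanesModel(a_plus=0.05, b_plus=0.08, d_plus=3.0,
                                a_minus=0.04, b_minus=0.02, d_minus=-8.0,
                                theta_m_H=-0.5, theta_q_H=600.0,
                                theta_m_rho=-2.0, theta_q_rho=400.0)

    def test_below_rheobase_is_zero(self, model):
        assert evaluate(model, 0.0, 100.0) == 0.0

    def test_above_boundary_is_plus_plane(self, model):
        v = evaluate(model, 100.0, 800.0)
        assert v == pytest.approx(0.05 * 100 + 0.08 * 800 + 3.0)

    def test_between_lines_is_minus_plane(self, model):
        v = evaluate(model, 100.0, 300.0)
        assert v == pytest.approx(0.04 * 100 + 0.02 * 300 - 8.0)

    def test_theta_zero_belongs_to_active_side(self, model):
        Is = 100.0
        Id = model.theta_m_H * Is + model.theta_q_H
        v = evaluate(model, Is, Id)
        assert v == pytest.approx(model.a_plus * Is + model.b_plus * Id
                                  + model.d_plus)

    def test_discontinuity_equals_plane_gap(self, model):
        Is = 200.0
        Id_b = model.theta_m_H * Is + model.theta_q_H
        above = evaluate(model, Is, Id_b)
        below = evaluate(model, Is, Id_b - 1e-9)
        plus = model.a_plus * Is + model.b_plus * Id_b + model.d_plus
        minus = model.a_minus * Is + model.b_minus * Id_b + model.d_minus
        assert above - below == pytest.approx(plus - minus, abs=1e-6)


class TestEndToEnd:
    def test_ten_parameter_round_trip(self):
        """Surface generated from a known model refits to the same model."""
        surf, true = planar_surface(step=20.0)
        fitted = fit_thetaplanes(surf, nu_low=true.nu_low)
        for name in ("a_plus", "b_plus", "d_plus", "a_minus", "b_minus", "d_minus"):
            assert getattr(fitted, name) == pytest.approx(getattr(true, name),
                                                          abs=1e-6)
        assert fitted.theta_m_H == pytest.approx(true.theta_m_H, abs=0.05)
        assert fitted.theta_q_H == pytest.approx(true.theta_q_H, abs=20.0)
        assert fitted.theta_m_rho == pytest.approx(true.theta_m_rho, abs=0.05)
        assert fitted.theta_q_rho == pytest.approx(true.theta_q_rho, abs=20.0)

    def test_report_zero_on_exact_surface(self):
        surf, true = planar_surface(step=20.0)
        fitted = fit_thetaplanes(surf, nu_low=true.nu_low)
        rep = fit_report(surf, fitted)
        assert rep["plus"]["max_abs_err"] < 1e-6
        assert rep["minus"]["max_abs_err"] < 1e-6

    def test_report_excludes_band(self):
        surf, true = planar_surface(step=20.0)
        fitted = fit_thetaplanes(surf, nu_low=true.nu_low, I_th=300.0)
        rep = fit_report(surf, fitted)
        II_s, _ = np.meshgrid(surf.Is_grid, surf.Id_grid, indexing="ij")
        masks = compute_masks(surf, fitted.nu_low, fitted.I_th)
        assert rep["overall"]["n"] == int((masks[0] | masks[1]).sum())
        assert not (masks[0] | masks[1])[surf.Is_grid > 300.0].any()

    def test_json_round_trip(self, tmp_path):
        _, model = planar_surface()
        p = tmp_path / "tp.json"
        model.to_json(p)
        assert ThetaPlanesModel.from_json(p) == model
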