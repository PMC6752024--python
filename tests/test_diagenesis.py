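"""Reaction-transport model: closed forms, structure, budgets, calibration."""

import numpy as np
import pytest
from dataclasses import replace

from sedpep.diagenesis import (
    DiagenesisParams,
    calibrate_model,
    ch4_budget,
    oc_flux_partition,
    oc_oxidation_summary,
    om_profile,
    so4_budget,
    solve_solutes,
    stoichiometric_factor,
)
from sedpep.errors import DomainError
from sedpep.profiles import DepthProfile


class TestStoichiometry:
    def test_electron_balance_factor(self):
        # carbon at state s releases (4 - s) electrons; sulfate accepts 8
        assert stoichiometric_factor(-0.7) == pytest.approx(4.7 / 8)
        assert stoichiometric_factor(0.0) == pytest.approx(0.5)

    def test_degenerate_state_rejected(self):
        with pytest.raises(DomainError):
            stoichiometric_factor(4.0)

    def test_flux_partition_arithmetic(self):
        c_flux, g1, g2 = oc_flux_partition(10.0, 0.0, ox_state=-0.7,
                                           f_partition=0.5, omega=0.3)
        assert c_flux == pytest.approx(10.0 / 0.5875, rel=1e-9)
        assert g1 == g2 == pytest.approx(0.5 * c_flux / 0.3)


class TestOmProfile:
    def test_boundary_identity(self):
        p = DiagenesisParams()
        g1, g2 = om_profile(p, [p.z_top])
        _, g1_top, g2_top = oc_flux_partition(p.so4_flux_top, p.ch4_burial_bottom,
                                              p.ox_state, p.f_partition, p.omega)
        assert g1[0] == pytest.approx(g1_top)
        assert g2[0] == pytest.approx(g2_top)

    def test_one_e_folding_length(self):
        p = DiagenesisParams(k1=0.01, k2=0.001, omega=0.3)
        g1, _ = om_profile(p, [p.z_top, p.z_top + 30.0])
        assert g1[1] / g1[0] == pytest.approx(np.exp(-1), rel=1e-12)

    def test_labile_fraction_vanishes_while_refractory_persists(self):
        p = DiagenesisParams(k1=1.0, k2=0.001, f_partition=0.5, omega=0.3)
        z = np.linspace(p.z_top, 60.0, 100)
        g1, g2 = om_profile(p, z)
        deep = z > 15.0
        assert np.all(g1[deep] / g1[0] < 1e-6)
        assert np.all(g2[deep] / g2[0] > 0.5)


class TestSolver:
    def test_smtz_structure_with_default_parameters(self):
        sol = solve_solutes(DiagenesisParams())
        # sulfate decreases monotonically away from the sediment-water interface
        assert np.all(np.diff(sol.so4) <= 1e-9)
        # methane stays near zero while sulfate is present (well below its
        # deep maximum, and negligible against the sulfate scale), then
        # builds up below the transition
        shallow = sol.so4 > 1.0
        assert sol.ch4[shallow].max() < 0.2 * sol.ch4.max()
        assert sol.ch4[shallow].max() < 0.01 * sol.params.so4_top
        smtz = sol.sulfate_depletion_depth()
        assert 30.0 < smtz < 55.0
        deep = sol.grid > smtz + 20
        assert np.all(np.diff(sol.ch4[deep]) >= -1e-9)

    def test_oxidation_rate_nonincreasing(self):
        sol = solve_solutes(DiagenesisParams())
        assert np.all(np.diff(sol.r_c) <= 0)
        assert np.allclose(sol.r_c, sol.params.k1 * sol.g1 + sol.params.k2 * sol.g2)

    def test_concentrations_nonnegative(self):
        sol = solve_solutes(DiagenesisParams())
        assert sol.so4.min() >= 0 and sol.ch4.min() >= 0

    def test_grid_refinement_convergence_order(self):
        p = DiagenesisParams()
        sols = {h: solve_solutes(replace(p, grid_step=h)) for h in (1.0, 0.5, 0.25)}
        z = sols[1.0].grid
        e1 = np.max(np.abs(sols[1.0].so4 - np.interp(z, sols[0.5].grid, sols[0.5].so4)))
        e2 = np.max(np.abs(np.interp(z, sols[0.5].grid, sols[0.5].so4)
                           - np.interp(z, sols[0.25].grid, sols[0.25].so4)))
        order = np.log2(e1 / e2)
        assert order >= 1.8
        # halving the default spacing moves the profile by <0.1% of the scale
        assert e2 / p.so4_top < 1e-3


class TestOxidationSummary:
    def test_identity_at_reference(self):
        sol = solve_solutes(DiagenesisParams())
        assert oc_oxidation_summary(sol, 4.5, 4.5) == pytest.approx(100.0)

    def test_single_g_closed_form_ratio(self):
        # k (z_q - z_r) / omega = ln(1000) makes the deep rate exactly 0.1%
        k = np.log(1000.0) * 0.3 / 78.0
        p = DiagenesisParams(k1=k, k2=1e-9, f_partition=1 - 1e-9,
                             k_aom=0.0, k_so4=0.0, so4_flux_top=20.0,
                             ch4_burial_bottom=0.0)
        sol = solve_solutes(p)
        assert oc_oxidation_summary(sol, 4.5, 82.5) == pytest.approx(0.1, rel=1e-3)

    def test_two_g_limit_approaches_refractory_exponential(self):
        p = DiagenesisParams(k1=1.0, k2=0.01, f_partition=0.5)
        sol = solve_solutes(p)
        expected = (1 - p.f_partition) * p.k2 * np.exp(-p.k2 * 78.0 / p.omega) \
            / (p.f_partition * p.k1 + (1 - p.f_partition) * p.k2) * 100
        assert oc_oxidation_summary(sol, 4.5, 82.5) == pytest.approx(expected, rel=1e-3)

    def test_depth_outside_grid_rejected(self):
        sol = solve_solutes(DiagenesisParams())
        with pytest.raises(DomainError):
            oc_oxidation_summary(sol, 4.5, 500.0)


class TestBudgets:
    def test_sulfate_and_methane_budgets_consistent_at_default_grid(self):
        sol = solve_solutes(DiagenesisParams())
        assert so4_budget(sol)["closure_rel_error"] < 0.01
        assert ch4_budget(sol)["closure_rel_error"] < 0.05


class TestCalibrationRobustness:
    def test_unphysical_increasing_sulfate_warns_not_crashes(self):
        z = np.arange(4.5, 120.0, 10.0)
        so4 = DepthProfile(z, np.linspace(2.0, 14.0, z.size))  # increasing downcore
        ch4 = DepthProfile(z, np.linspace(0.0, 0.5, z.size))
        with pytest.warns(UserWarning, match="incompatible|variance"):
            res = calibrate_model(so4, ch4, n_polish=1, max_nfev=15)
        assert res.sse > 0
        assert res.quality_warning is not None

    def test_too_few_observations_rejected(self):
        z = np.array([4.5, 20.0, 40.0])
        p = DepthProfile(z, np.ones(3))
        with pytest.raises(DomainError):
            calibrate_model(p, p)
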