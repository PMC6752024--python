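"""Assay reduction, Michaelis-Menten fitting, aggregation and comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedpep.errors import DomainError, InvalidDesignError
from sedpep.kinetics import (
    CalibrationCurve,
    SaturationAssay,
    compare_substrates,
    compute_v0,
    fit_assay,
    fit_michaelis_menten,
    KineticFit,
    ratio_profile,
    sum_vmax,
    vmax_proxy,
)
from sedpep.profiles import DepthProfile
from sedpep.synthetic_data import KineticGroundTruth, gen_saturation_assay

from conftest import v0_table_from_law


class TestComputeV0:
    def test_hand_calculated_rate(self, simple_assay, calib):
        # dF=40, slope=2 F/uM -> 20 uM AMC; x4.5 ml / 0.5 g / 3 h = 60 nmol/g/h
        v0 = compute_v0(simple_assay, calib)
        assert np.allclose(v0["v0"], 60.0)

    def test_zero_drift_gives_zero_rate(self, simple_assay, calib):
        simple_assay.records["fluor_t1"] = simple_assay.records["fluor_t0"]
        v0 = compute_v0(simple_assay, calib)
        assert np.allclose(v0["v0"], 0.0)
        assert not v0["negative_drift"].any()

    def test_negative_drift_preserved_and_flagged(self, simple_assay, calib):
        simple_assay.records.loc[0, "fluor_t1"] = 90.0  # below t0 reading
        v0 = compute_v0(simple_assay, calib)
        assert v0.loc[0, "v0"] < 0
        assert bool(v0.loc[0, "negative_drift"])

    def test_missing_calibration_rejected(self, simple_assay):
        from sedpep.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            compute_v0(simple_assay, None)

    def test_nonpositive_elapsed_time_rejected(self, simple_assay):
        rec = simple_assay.records.copy()
        rec["t1_h"] = rec["t0_h"]
        with pytest.raises(DomainError):
            SaturationAssay("X", 4.5, rec)


class TestMichaelisMentenFit:
    def test_noiseless_recovery_to_numerical_tolerance(self):
        tab = v0_table_from_law(100.0, 50.0, concs=(25, 50, 100, 200, 300))
        fit = fit_michaelis_menten(tab)
        assert fit.fit_ok
        assert fit.vmax == pytest.approx(100.0, rel=1e-6)
        assert fit.km == pytest.approx(50.0, rel=1e-6)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        tab = v0_table_from_law(310.0, 138.0, noise=rng.normal(0, 10, 6))
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = fit_michaelis_menten(tab)
        f2 = fit_michaelis_menten(shuffled)
        assert f1.vmax == pytest.approx(f2.vmax, rel=1e-6)
        assert f1.km == pytest.approx(f2.km, rel=1e-6)

    @given(scale=st.floats(min_value=0.25, max_value=4.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_km_is_scale_covariant(self, scale):
        # doubling all substrate concentrations and Km doubles the estimate,
        # Vmax is unchanged
        base = np.array([25, 50, 75, 100, 200, 300], dtype=float)
        tab = v0_table_from_law(100.0, 50.0 * scale, concs=base * scale)
        fit = fit_michaelis_menten(tab)
        assert fit.vmax == pytest.approx(100.0, rel=1e-5)
        assert fit.km == pytest.approx(50.0 * scale, rel=1e-5)

    def test_saturated_plateau_triggers_fallback(self):
        tab = pd.DataFrame({"conc_um": [25.0, 50.0, 100.0, 200.0, 300.0],
                            "v0": [80.0] * 5,
                            "treatment": ["live"] * 5})
        fit = fit_michaelis_menten(tab)
        assert fit.fallback_used
        assert fit.km is None
        assert fit.vmax == pytest.approx(80.0)

    def test_all_zero_rates_not_fit(self):
        tab = pd.DataFrame({"conc_um": [25.0, 50.0, 100.0, 200.0],
                            "v0": [0.0] * 4, "treatment": ["live"] * 4})
        fit = fit_michaelis_menten(tab)
        assert not fit.fit_ok and not fit.fallback_used
        assert fit.vmax == 0.0

    def test_too_few_concentrations_rejected(self):
        tab = v0_table_from_law(100, 50, concs=(25, 50, 100))
        with pytest.raises(InvalidDesignError):
            fit_michaelis_menten(tab)

    def test_round_trip_through_generated_assay(self, calib):
        gt = KineticGroundTruth("Gly-AMC", 28.5, vmax_true=840.0, km_true=120.0,
                                noise_sd=0.0, seed=11)
        fit = fit_assay(gen_saturation_assay(gt), calib)
        assert fit.vmax == pytest.approx(840.0, rel=1e-6)
        assert fit.km == pytest.approx(120.0, rel=1e-6)

    def test_killed_subtraction_reduces_rate(self, calib):
        gt = KineticGroundTruth("X", 4.5, 100, 50, noise_sd=0, killed_fraction=0.2)
        assay = gen_saturation_assay(gt)
        raw = fit_assay(assay, calib)
        corrected = fit_assay(assay, calib, subtract_killed=True)
        assert corrected.vmax == pytest.approx(0.8 * raw.vmax, rel=1e-6)

    def test_vmax_proxy_single_concentration(self):
        tab = pd.DataFrame({"conc_um": [400.0, 400.0, 400.0],
                            "v0": [90.0, 100.0, 110.0],
                            "treatment": ["live"] * 3})
        f = vmax_proxy(tab)
        assert f.fallback_used and f.km is None
        assert f.vmax == pytest.approx(100.0)
        assert f.vmax_se == pytest.approx(10.0 / np.sqrt(3))


def _fit(sub, depth, vmax, se, km=100.0, km_se=10.0):
    return KineticFit(sub, depth, vmax, se, km, km_se, True, False, 1.0, 6)


class TestSumVmax:
    def test_single_fit_identity(self):
        s = sum_vmax([_fit("A", 4.5, 100.0, 5.0)])
        assert s.profile.values[0] == 100.0
        assert s.profile.errors[0] == 5.0

    def test_quadrature_error(self):
        s = sum_vmax([_fit("A", 4.5, 3.0, 0.4), _fit("B", 4.5, 4.0, 0.3)])
        assert s.profile.values[0] == pytest.approx(7.0)
        assert s.profile.errors[0] == pytest.approx(0.5)

    def test_normalization_to_reference_depth(self):
        fits = [_fit("A", 4.5, 9090.0, 50.0), _fit("A", 82.5, 1240.0, 30.0)]
        s = sum_vmax(fits, reference_depth=4.5)
        assert s.normalized.values[0] == pytest.approx(1.0)
        assert s.normalized.values[1] == pytest.approx(1240.0 / 9090.0)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            sum_vmax([])


class TestCompareSubstrates:
    def _population(self, rng, means, n=5, sd=0.05):
        fits = []
        for sub, mu in means.items():
            for d in range(n):
                vmax = 10 ** rng.normal(np.log10(mu), sd)
                km = 10 ** rng.normal(2.0, sd)
                fits.append(_fit(sub, float(d), vmax, vmax * 0.05, km, km * 0.05))
        return fits

    def test_forced_separation_gets_disjoint_letters(self):
        rng = np.random.default_rng(0)
        comp = compare_substrates(self._population(rng, {"A": 1000.0, "B": 100.0}, sd=0.01))
        assert set(comp.vmax_letters["A"]) & set(comp.vmax_letters["B"]) == set()

    def test_one_fast_two_equivalent_groups(self):
        rng = np.random.default_rng(1)
        comp = compare_substrates(
            self._population(rng, {"A": 5000.0, "B": 100.0, "C": 100.0}, sd=0.02))
        assert set(comp.vmax_letters["A"]) & set(comp.vmax_letters["B"]) == set()
        assert set(comp.vmax_letters["B"]) & set(comp.vmax_letters["C"])

    def test_null_distribution_shares_one_letter(self):
        # all substrates drawn from one distribution: a single shared letter
        # except for the nominal type-I error rate
        shared = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            comp = compare_substrates(
                self._population(rng, {"A": 300.0, "B": 300.0, "C": 300.0}, sd=0.2))
            if all(v == "a" for v in comp.vmax_letters.values()):
                shared += 1
        assert shared / n_seeds >= 0.90

    def test_small_groups_excluded(self):
        fits = self._population(np.random.default_rng(2), {"A": 100.0, "B": 100.0})
        fits.append(_fit("C", 0.0, 50.0, 5.0))  # single observation
        with pytest.warns(UserWarning, match="excluding"):
            comp = compare_substrates(fits)
        assert "C" not in comp.vmax_letters


class TestRatioProfile:
    def test_identical_profiles_give_unit_ratio_and_zero_slope(self):
        z = np.array([0.0, 20.0, 40.0, 60.0])
        a = DepthProfile(z, np.array([2.0, 3.0, 4.0, 5.0]))
        res = ratio_profile(a, a)
        assert np.allclose(res.ratio.values, 1.0)
        assert res.regression.slope == pytest.approx(0.0, abs=1e-12)

    def test_relative_error_quadrature(self):
        z = np.array([0.0, 10.0, 20.0])
        a = DepthProfile(z, np.full(3, 10.0), np.full(3, 1.0))
        b = DepthProfile(z, np.full(3, 5.0), np.full(3, 0.5))
        res = ratio_profile(a, b)
        assert np.allclose(res.ratio.errors / res.ratio.values,
                           np.sqrt(2) * 0.1)

    def test_zero_denominator_dropped(self):
        z = np.array([0.0, 10.0, 20.0, 30.0])
        a = DepthProfile(z, np.ones(4))
        b = DepthProfile(z, np.array([1.0, 0.0, 1.0, 1.0]))
        with pytest.warns(UserWarning, match="zero denominator"):
            res = ratio_profile(a, b)
        assert len(res.ratio) == 3

    def test_regression_refused_below_three_depths(self):
        z = np.array([0.0, 10.0])
        a = DepthProfile(z, np.ones(2))
        with pytest.warns(UserWarning, match="regression refused"):
            res = ratio_profile(a, a)
        assert res.regression is None
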