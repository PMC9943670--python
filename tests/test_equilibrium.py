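"""Mass-action dimer model, per-lane omega estimator, titration fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgpal.equilibrium import (
    NOT_DETERMINED,
    BindingParameters,
    IdentifiabilityWarning,
    LaneQuantification,
    SpeciesFractions,
    TitrationCondition,
    dual_probe_preference,
    estimate_omega,
    fit_titration,
    omega_from_fractions,
    quantify_lane,
    solve_species,
)
from cpgpal.simulate import simulate_titration

from conftest import bisection_free_protein, fractions_from_free_protein


class TestSolveSpecies:
    def test_omega_zero_forbids_dimer(self):
        fr = solve_species(BindingParameters(100, 0.0), 500, 50)
        assert fr.f_dim == 0.0

    def test_saturation_limit(self):
        fr = solve_species(BindingParameters(100, 1.0), 1e7, 50)
        assert fr.f_dim > 0.999

    def test_negligible_probe_matches_binomial(self):
        # with no depletion, per-site occupancy theta = p/(p+Kd) = 0.5 and
        # the two half-sites fill independently: (1-t)^2, 2t(1-t), t^2
        fr = solve_species(BindingParameters(100, 1.0), 100, 1e-6)
        assert fr.f_free == pytest.approx(0.25, abs=1e-5)
        assert fr.f_mon == pytest.approx(0.5, abs=1e-5)
        assert fr.f_dim == pytest.approx(0.25, abs=1e-5)

    def test_zero_protein_all_free(self):
        fr = solve_species(BindingParameters(100, 5.0), 0.0, 50)
        assert fr.f_free == 1.0

    @pytest.mark.parametrize("bad", [(-5, 50), (float("nan"), 50), (100, 0), (100, -1)])
    def test_invalid_inputs_raise(self, bad):
        p_tot, d_tot = bad
        with pytest.raises(ValueError):
            solve_species(BindingParameters(100, 1.0), p_tot, d_tot)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        kd=st.floats(1.0, 1e4),
        omega=st.floats(0.0, 100.0),
        p_tot=st.floats(0.1, 5e3),
        d_tot=st.floats(0.1, 500.0),
    )
    def test_normalization_and_conservation(self, kd, omega, p_tot, d_tot):
        fr = solve_species(BindingParameters(kd, omega), p_tot, d_tot)
        assert abs(fr.f_free + fr.f_mon + fr.f_dim - 1.0) < 1e-9
        # back out bound protein from fractions and check conservation
        p = bisection_free_protein(kd, omega, p_tot, d_tot)
        bound = d_tot * (fr.f_mon + 2 * fr.f_dim)
        assert abs(p + bound - p_tot) < 1e-6 * max(p_tot, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        kd=st.floats(1.0, 1e4),
        omega=st.floats(0.0, 100.0),
        d_tot=st.floats(0.1, 500.0),
        data=st.data(),
    )
    def test_dimer_fraction_monotone_in_protein(self, kd, omega, d_tot, data):
        p1 = data.draw(st.floats(0.1, 2e3))
        p2 = data.draw(st.floats(0.1, 2e3))
        lo, hi = sorted((p1, p2))
        params = BindingParameters(kd, omega)
        f_lo = solve_species(params, lo, d_tot).f_dim
        f_hi = solve_species(params, hi, d_tot).f_dim
        assert f_hi >= f_lo - 1e-9

    def test_agrees_with_dense_bisection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            kd = 10 ** rng.uniform(0, 4)
            omega = 10 ** rng.uniform(-2, 2)
            p_tot = 10 ** rng.uniform(-1, 3.5)
            d_tot = 10 ** rng.uniform(-1, 2.7)
            fr = solve_species(BindingParameters(kd, omega), p_tot, d_tot)
            p = bisection_free_protein(kd, omega, p_tot, d_tot)
            expected = fractions_from_free_protein(kd, omega, p)
            assert np.allclose(fr.as_array(), expected, atol=1e-8)


class TestQuantifyLane:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ((10, 10, 0), (0.5, 0.5, 0.0)),
            ((0, 0, 7), (0.0, 0.0, 1.0)),
            ((30, 50, 20), (0.3, 0.5, 0.2)),
        ],
    )
    def test_normalization(self, intensities, expected):
        lane = quantify_lane(intensities, protein_total=100)
        assert lane.fractions.as_array() == pytest.approx(expected)

    def test_empty_lane_rejected(self):
        with pytest.raises(ValueError, match="empty lane"):
            quantify_lane((0, 0, 0), 100)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            quantify_lane((-1, 5, 5), 100)


class TestEstimateOmega:
    def test_independent_sites_give_unity(self):
        lane = quantify_lane((0.25, 0.5, 0.25), 100)
        est = estimate_omega([lane])
        assert est.per_lane_omega[0] == pytest.approx(1.0)

    def test_inverts_model_exactly(self):
        # estimator applied to model output must return the planted omega
        for omega in (0.1, 1.0, 3.0, 10.0):
            for p_tot in (50, 100, 200, 400):
                fr = solve_species(BindingParameters(100, omega), p_tot, 50)
                if min(fr.f_free, fr.f_mon, fr.f_dim) >= 0.05:
                    assert omega_from_fractions(fr) == pytest.approx(omega, abs=1e-6)

    def test_low_fraction_lane_excluded(self):
        good = quantify_lane((0.3, 0.5, 0.2), 100)
        bad = quantify_lane((0.93, 0.04, 0.03), 200)
        est = estimate_omega([good, bad])
        assert est.included_lanes == (True, False)
        assert est.n == 1

    def test_not_determined_when_no_lane_passes(self):
        # strongly negative cooperativity: dimer band never reaches 0.05
        bad = quantify_lane((0.9, 0.08, 0.02), 100)
        est = estimate_omega([bad])
        assert est.mean == NOT_DETERMINED
        assert est.sd == NOT_DETERMINED
        assert not est.determined

    def test_threshold_domain(self):
        lane = quantify_lane((1, 1, 1), 100)
        with pytest.raises(ValueError):
            estimate_omega([lane], inclusion_threshold=0.5)
        with pytest.raises(ValueError):
            estimate_omega([lane], inclusion_threshold=0.0)


class TestFitTitration:
    def test_recovers_planted_parameters_noiseless(
        self, reference_params, titration_condition
    ):
        table = simulate_titration(
            reference_params, titration_condition, noise_cv=0.0, seed=0
        )
        lanes = [
            quantify_lane(
                (r.intensity_free, r.intensity_mon, r.intensity_dim),
                r.protein_total_nM,
            )
            for r in table.itertuples()
        ]
        fit = fit_titration(lanes, titration_condition)
        assert fit.params.kd_half_site == pytest.approx(100.0, rel=1e-3)
        assert fit.params.omega == pytest.approx(5.0, rel=1e-3)

    def test_noisy_recovery_median_error(self, reference_params, titration_condition):
        rel_errors = []
        for seed in range(10):
            table = simulate_titration(
                reference_params, titration_condition, noise_cv=0.05, seed=seed
            )
            lanes = [
                quantify_lane(
                    (r.intensity_free, r.intensity_mon, r.intensity_dim),
                    r.protein_total_nM,
                )
                for r in table.itertuples()
            ]
            fit = fit_titration(lanes, titration_condition)
            rel_errors.append(abs(fit.params.omega - 5.0) / 5.0)
        assert float(np.median(rel_errors)) < 0.20

    def test_all_free_triggers_identifiability_warning(self, titration_condition):
        lanes = [
            quantify_lane((0.999, 0.0005, 0.0005), p)
            for p in titration_condition.protein_totals
        ]
        with pytest.warns(IdentifiabilityWarning):
            fit_titration(lanes, titration_condition)

    def test_too_few_lanes_rejected(self, titration_condition):
        lanes = [quantify_lane((1, 1, 1), 25)]
        with pytest.raises(ValueError):
            fit_titration(lanes, titration_condition)


class TestDualProbePreference:
    def test_identical_lane_sets_zero_index(self):
        lanes = [quantify_lane((3, 2, 1), p) for p in (50, 100, 200)]
        index, mean = dual_probe_preference(lanes, lanes)
        assert np.allclose(index, 0.0)
        assert mean == 0.0

    def test_full_dimer_vs_full_free_gives_one(self):
        a = [quantify_lane((0, 0, 1), 100)]
        b = [quantify_lane((1, 0, 0), 100)]
        index, mean = dual_probe_preference(a, b)
        assert index[0] == 1.0 and mean == 1.0

    def test_opposite_factor_preferences_have_opposite_signs(self):
        # an Oct4-like factor prefers the CpG palindrome, a Brn2-like
        # factor the MORE; the preference index must flip sign between them
        cond = TitrationCondition(50.0, (25.0, 50.0, 100.0, 200.0, 400.0, 800.0))

        def lanes(omega):
            params = BindingParameters(100.0, omega)
            return [
                quantify_lane(solve_species(params, p, 50.0).as_array(), p)
                for p in cond.protein_totals
            ]

        oct4_index, oct4_mean = dual_probe_preference(lanes(8.0), lanes(2.0))
        brn2_index, brn2_mean = dual_probe_preference(lanes(0.3), lanes(20.0))
        assert oct4_mean > 0 > brn2_mean

    def test_mismatched_concentrations_rejected(self):
        a = [quantify_lane((1, 1, 1), 100)]
        b = [quantify_lane((1, 1, 1), 200)]
        with pytest.raises(ValueError, match="mismatched"):
            dual_probe_preference(a, b)


class TestDomainTypes:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SpeciesFractions(0.5, 0.5, 0.5)

    def test_protein_series_must_increase(self):
        with pytest.raises(ValueError):
            TitrationCondition(50.0, (100.0, 50.0))

    def test_parameters_positive(self):
        with pytest.raises(ValueError):
            BindingParameters(-1.0, 1.0)
        with pytest.raises(ValueError):
            BindingParameters(100.0, -0.5)
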