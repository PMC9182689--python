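import numpy as np
import pytest

from screenq.network import NetworkValidationError, ServiceSpec
from screenq.screening import (
    ScreeningScenario,
    SubgroupKey,
    SubgroupParams,
    apply_morbidity,
    apply_mortality,
    build_no_screening_network,
    build_screening_network,
    lifetime_gain,
    net_benefit_with_specificity,
    per_screen_benefit,
)
from screenq.stationary import expected_sojourn, solve_traffic
from screenq.network import validate_network


class TestNetworkConstruction:
    def test_screening_network_routing_and_rates(self, subgroup_params, scenario):
        net = build_screening_network(subgroup_params, scenario)
        assert validate_network(net) == []
        R = net.routing.entries
        np.testing.assert_allclose(R[0], [0.0, 0.3, 0.6])
        sol = solve_traffic(net)
        eta_mo = 100.0 / 12.0
        np.testing.assert_allclose(
            sol.arrival_rates, [eta_mo, 0.3 * eta_mo, 0.6 * eta_mo], rtol=1e-12
        )

    def test_partial_detection_splits_screenable_mass(self, subgroup_params):
        sc = ScreeningScenario(detection_prob=0.5, effectiveness=0.75)
        net = build_screening_network(subgroup_params, sc)
        np.testing.assert_allclose(net.routing.entries[0], [0.0, 0.15, 0.75])

    def test_zero_detection_collapses_to_counterfactual(self, subgroup_params):
        sc = ScreeningScenario(detection_prob=0.0, effectiveness=0.75)
        with_screen = build_screening_network(subgroup_params, sc)
        without = build_no_screening_network(subgroup_params)
        np.testing.assert_allclose(
            with_screen.routing.entries, without.routing.entries
        )
        np.testing.assert_allclose(
            solve_traffic(with_screen).loads, solve_traffic(without).loads
        )

    def test_no_screening_early_treatment_queue_is_empty(self, subgroup_params):
        sol = solve_traffic(build_no_screening_network(subgroup_params))
        assert sol.loads[1] == 0.0

    def test_no_screening_sojourn_closed_form(self, subgroup_params):
        # 1/mu1 + (r13 + r12)/mu3 months
        expected = 24.0 + 0.9 * 12.0
        got = expected_sojourn(build_no_screening_network(subgroup_params))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_degenerate_early_survival_is_an_error(self, subgroup_params):
        sc = ScreeningScenario(detection_prob=1.0, effectiveness=0.0)
        with pytest.raises(NetworkValidationError):
            build_screening_network(subgroup_params, sc)


class TestLifetimeGain:
    def test_worked_example_gain(self, subgroup_params, scenario):
        # r12 * (e*L - 1/mu3) = 0.3 * (20 - 1) years
        assert lifetime_gain(subgroup_params, scenario) == pytest.approx(5.7, rel=1e-12)

    def test_gain_per_detected_conditions_on_detection(self, subgroup_params, scenario):
        per_patient = lifetime_gain(subgroup_params, scenario)
        per_detected = lifetime_gain(subgroup_params, scenario, per_detected=True)
        assert per_detected == pytest.approx(per_patient / 0.3, rel=1e-12)

    def test_gain_zero_when_early_survival_equals_late_path(self, subgroup_params):
        # e*L == 1/mu3 = 12 months -> no benefit
        sc = ScreeningScenario(
            detection_prob=1.0, effectiveness=1.0 / subgroup_params.cond_life_expectancy
        )
        assert lifetime_gain(subgroup_params, sc) == pytest.approx(0.0, abs=1e-12)

    def test_gain_monotone_in_detection_and_effectiveness(self, subgroup_params):
        grid = np.linspace(0.05, 1.0, 5)
        gains = np.array(
            [
                [
                    lifetime_gain(
                        subgroup_params,
                        ScreeningScenario(detection_prob=d, effectiveness=e),
                    )
                    for e in grid
                ]
                for d in grid
            ]
        )
        assert np.all(np.diff(gains, axis=0) >= -1e-12)  # in d
        assert np.all(np.diff(gains, axis=1) >= -1e-12)  # in e

    def test_gain_linear_in_effectiveness_at_fixed_detection(self, subgroup_params):
        es = np.linspace(0.1, 1.0, 7)
        gains = [
            lifetime_gain(
                subgroup_params, ScreeningScenario(detection_prob=0.8, effectiveness=e)
            )
            for e in es
        ]
        second_diff = np.diff(gains, n=2)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-10)


class TestPerScreenBenefit:
    def test_direct_arithmetic(self):
        params = SubgroupParams(
            diagnosis_rate=25.0,  # pool rho1 = 25 * 2y = 50
            mean_early_sojourn=24.0,
            death_frac=0.1,
            screen_frac=0.3,
            progress_frac=0.6,
            mean_late_survival=12.0,
            treated_fraction=0.5,
            mean_diag_to_treatment=1.0,
            cond_life_expectancy=26.7,
        )
        got = per_screen_benefit(10.0, params, 10**6)
        assert got == pytest.approx(10.0 * 365.0 * 50.0 / 1e6, rel=1e-12)

    def test_zero_gain_zero_benefit(self, subgroup_params):
        assert per_screen_benefit(0.0, subgroup_params, 1000) == 0.0

    def test_doubling_population_halves_benefit(self, subgroup_params):
        one = per_screen_benefit(5.0, subgroup_params, 10_000)
        two = per_screen_benefit(5.0, subgroup_params, 20_000)
        assert one == pytest.approx(2.0 * two, rel=1e-12)

    def test_zero_population_rejected(self, subgroup_params):
        with pytest.raises(ValueError):
            per_screen_benefit(1.0, subgroup_params, 0)

    def test_per_patient_and_per_screen_rankings_can_differ(self, scenario):
        """A rare-disease young group can beat an older group per patient
        while losing per screen, because its standing pool is tiny."""
        young = SubgroupParams(
            diagnosis_rate=5.0, mean_early_sojourn=24.0, death_frac=0.0,
            screen_frac=1.0, progress_frac=0.0, mean_late_survival=12.0,
            treated_fraction=0.5, mean_diag_to_treatment=1.0,
            cond_life_expectancy=50.0,
        )
        old = SubgroupParams(
            diagnosis_rate=500.0, mean_early_sojourn=24.0, death_frac=0.0,
            screen_frac=1.0, progress_frac=0.0, mean_late_survival=12.0,
            treated_fraction=0.5, mean_diag_to_treatment=1.0,
            cond_life_expectancy=12.0,
        )
        pop = 10**6
        g_young, g_old = (lifetime_gain(p, scenario) for p in (young, old))
        s_young = per_screen_benefit(g_young, young, pop)
        s_old = per_screen_benefit(g_old, old, pop)
        assert g_young > g_old and s_young < s_old


class TestMorbidityMortality:
    @pytest.mark.parametrize(
        "years, q, frac, expected",
        [(10.0, 1.0, 1.0, 10.0), (10.0, 0.0, 1.0, 0.0), (10.0, 0.8, 0.2, 9.6)],
    )
    def test_quality_adjustment_arithmetic(self, years, q, frac, expected):
        assert apply_morbidity(years, q, frac) == pytest.approx(expected, rel=1e-12)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            apply_morbidity(10.0, 0.5, 1.2)

    def test_zero_mortality_returns_original_spec(self):
        base = ServiceSpec.lognormal(120.0, 1.0)
        assert apply_mortality(base, 0.0) is base

    def test_certain_mortality_is_point_mass_at_one_month(self):
        out = apply_mortality(ServiceSpec.exponential(120.0), 1.0)
        assert out.mean == pytest.approx(1.0)

    def test_mixture_mean_is_linear(self):
        out = apply_mortality(ServiceSpec.exponential(120.0), 0.1)
        assert out.mean == pytest.approx(0.1 * 1.0 + 0.9 * 120.0, rel=1e-12)

    def test_mortality_lowers_gain(self, subgroup_params, scenario):
        risky = ScreeningScenario(
            detection_prob=1.0, effectiveness=0.75, mortality_prob=0.2
        )
        assert lifetime_gain(subgroup_params, risky) < lifetime_gain(
            subgroup_params, scenario
        )


class TestSpecificity:
    def test_no_false_positives_equals_gross_benefit(self, subgroup_params, scenario):
        net = net_benefit_with_specificity(subgroup_params, scenario, 10**6)
        gross = subgroup_params.diagnosis_rate * lifetime_gain(subgroup_params, scenario)
        assert net == pytest.approx(gross, rel=1e-12)

    def test_harmless_false_positives_do_not_reduce_benefit(self, subgroup_params):
        sc = ScreeningScenario(
            detection_prob=1.0, effectiveness=0.75,
            false_positive_rate=0.05, fp_survival_reduction=0.0,
        )
        gross = subgroup_params.diagnosis_rate * lifetime_gain(subgroup_params, sc)
        assert net_benefit_with_specificity(subgroup_params, sc, 10**7) == pytest.approx(
            gross, rel=1e-12
        )

    def test_large_healthy_population_can_make_net_negative(self, subgroup_params):
        sc = ScreeningScenario(
            detection_prob=1.0, effectiveness=0.75,
            false_positive_rate=0.01, confirmatory_specificity=0.9,
            fp_survival_reduction=0.05,
        )
        healthy = 10**7
        net = net_benefit_with_specificity(subgroup_params, sc, healthy)
        # agent-level bookkeeping oracle
        gross = subgroup_params.diagnosis_rate * lifetime_gain(subgroup_params, sc)
        fp_per_year = healthy * 1.0 * 0.01 * (1 - 0.9)
        loss = fp_per_year * 0.05 * subgroup_params.cond_life_expectancy
        assert net == pytest.approx(gross - loss, rel=1e-12)
        assert net < 0

    def test_negative_population_rejected(self, subgroup_params, scenario):
        with pytest.raises(ValueError):
            net_benefit_with_specificity(subgroup_params, scenario, -1)


class TestParameterValidation:
    def test_routing_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SubgroupParams(
                diagnosis_rate=1.0, mean_early_sojourn=1.0, death_frac=0.2,
                screen_frac=0.2, progress_frac=0.2, mean_late_survival=1.0,
                treated_fraction=0.5, mean_diag_to_treatment=1.0,
                cond_life_expectancy=10.0,
            )

    def test_scenario_probabilities_bounded(self):
        with pytest.raises(ValueError):
            ScreeningScenario(detection_prob=1.2, effectiveness=0.5)

    def test_subgroup_key_is_hashable_and_ordered(self):
        a = SubgroupKey("pancreas", "female", "Caucasian", "50-54")
        b = SubgroupKey("pancreas", "female", "Caucasian", "55-59")
        assert a < b and len({a, b, a}) == 2
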