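import math

import numpy as np
import pytest

from screenq.network import QueueNetwork, RoutingMatrix, ServiceSpec
from screenq.stationary import (
    StationaryModel,
    TrafficError,
    expected_sojourn,
    joint_pmf,
    marginal_pmf,
    marginal_tail,
    solve_traffic,
    stationary_model,
)


def _poisson_pmf_bruteforce(rho: float, n: int) -> float:
    """Term-by-term factorial evaluation, independent of scipy."""
    return math.exp(-rho) * rho**n / math.factorial(n)


class TestSolveTraffic:
    def test_tandem_closed_form(self, two_queue_net):
        sol = solve_traffic(two_queue_net)
        np.testing.assert_allclose(sol.arrival_rates, [10.0, 4.0])
        np.testing.assert_allclose(sol.loads, [60.0, 48.0])

    def test_single_queue_no_feedback(self):
        net = QueueNetwork(
            RoutingMatrix(np.zeros((1, 1))),
            np.array([3.0]),
            (ServiceSpec.exponential(4.0),),
        )
        sol = solve_traffic(net)
        assert sol.arrival_rates[0] == pytest.approx(3.0)
        assert sol.loads[0] == pytest.approx(12.0)

    def test_feedback_loop_matches_fixed_point_iteration(self):
        R = np.array([[0.0, 0.5, 0.2], [0.1, 0.0, 0.3], [0.0, 0.2, 0.0]])
        net = QueueNetwork(
            RoutingMatrix(R),
            np.array([2.0, 1.0, 0.5]),
            tuple(ServiceSpec.exponential(m) for m in (1.0, 2.0, 3.0)),
        )
        sol = solve_traffic(net)
        lam = net.exogenous_rates.copy()
        for _ in range(10_000):
            lam = net.exogenous_rates + lam @ R
        np.testing.assert_allclose(sol.arrival_rates, lam, rtol=1e-9)
        resid = sol.arrival_rates - net.exogenous_rates - sol.arrival_rates @ R
        assert np.linalg.norm(resid) < 1e-9 * np.linalg.norm(sol.arrival_rates)

    def test_singular_routing_raises_traffic_error(self):
        net = QueueNetwork(
            RoutingMatrix(np.eye(2)),
            np.array([1.0, 0.0]),
            (ServiceSpec.exponential(1.0), ServiceSpec.exponential(1.0)),
        )
        with pytest.raises((TrafficError, Exception)):
            solve_traffic(net)


class TestProductForm:
    def test_joint_pmf_factorizes_into_poisson_terms(self):
        model = StationaryModel(loads=np.array([2.0, 3.0]))
        expected = _poisson_pmf_bruteforce(2.0, 1) * _poisson_pmf_bruteforce(3.0, 2)
        assert joint_pmf(model, [1, 2]) == pytest.approx(expected, rel=1e-12)

    def test_empty_network_is_certainly_empty(self):
        model = StationaryModel(loads=np.array([0.0, 0.0]))
        assert joint_pmf(model, [0, 0]) == 1.0
        assert joint_pmf(model, [1, 0]) == 0.0

    def test_single_queue_pmf_at_zero(self):
        model = StationaryModel(loads=np.array([1.0]))
        assert joint_pmf(model, [0]) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_negative_counts_rejected(self):
        model = StationaryModel(loads=np.array([1.0]))
        with pytest.raises(ValueError):
            joint_pmf(model, [-1])

    def test_marginals_sum_to_one_with_matching_mean(self):
        model = StationaryModel(loads=np.array([2.5]))
        ks = np.arange(200)
        pmf = np.array([marginal_pmf(model, 0, int(k)) for k in ks])
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf * ks).sum() == pytest.approx(2.5, rel=1e-12)


class TestMarginalTail:
    def test_tail_at_zero_is_one_minus_pmf_at_zero(self):
        model = StationaryModel(loads=np.array([1.0]))
        assert marginal_tail(model, 0, 0.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("rho", [0.5, 1.0, 2.5, 10.0])
    @pytest.mark.parametrize("x", [0.0, 1.0, 4.0, 20.0, 2.7])
    def test_tail_matches_independent_partial_sum(self, rho, x):
        model = StationaryModel(loads=np.array([rho]))
        partial = sum(_poisson_pmf_bruteforce(rho, k) for k in range(math.floor(x) + 1))
        assert marginal_tail(model, 0, x) == pytest.approx(1 - partial, abs=1e-12)

    def test_tail_plus_partial_pmf_sum_is_one(self):
        model = StationaryModel(loads=np.array([3.3]))
        for x in (0, 2, 7):
            head = sum(marginal_pmf(model, 0, k) for k in range(x + 1))
            assert marginal_tail(model, 0, x) + head == pytest.approx(1.0, abs=1e-12)

    def test_zero_load_queue_never_exceeds_zero(self):
        model = StationaryModel(loads=np.array([0.0]))
        assert marginal_tail(model, 0, 0.0) == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            marginal_tail(StationaryModel(loads=np.array([1.0])), 0, -0.1)

    def test_tail_agrees_with_monte_carlo_exceedance(self):
        rng = np.random.default_rng(5)
        for rho, x in [(2.5, 4.0), (10.0, 20.0)]:
            draws = rng.poisson(rho, 1_000_000)
            freq = float((draws > x).mean())
            se = math.sqrt(freq * (1 - freq) / len(draws)) or 1e-6
            exact = marginal_tail(StationaryModel(loads=np.array([rho])), 0, x)
            assert abs(exact - freq) < 3 * se


class TestExpectedSojourn:
    def test_single_queue_equals_service_mean(self):
        net = QueueNetwork(
            RoutingMatrix(np.zeros((1, 1))),
            np.array([7.0]),
            (ServiceSpec.lognormal(9.0, 0.8),),
        )
        assert expected_sojourn(net) == pytest.approx(9.0, rel=1e-12)

    def test_three_state_screening_example(self):
        # 2y preclinical; 30% -> 20y early treatment, 60% -> 1y late survival
        R = np.array([[0.0, 0.3, 0.6], [0.0] * 3, [0.0] * 3])
        net = QueueNetwork(
            RoutingMatrix(R),
            np.array([1.0, 0.0, 0.0]),
            tuple(ServiceSpec.exponential(m) for m in (24.0, 240.0, 12.0)),
        )
        assert expected_sojourn(net) / 12.0 == pytest.approx(8.6, rel=1e-12)

    def test_sojourn_equals_absorbing_chain_path_expectation(self):
        # expected visits x mean service, via (I - R)^-1 on a looping net
        R = np.array([[0.0, 0.6], [0.3, 0.0]])
        means = np.array([5.0, 2.0])
        net = QueueNetwork(
            RoutingMatrix(R),
            np.array([1.0, 0.0]),
            tuple(ServiceSpec.exponential(m) for m in means),
        )
        start = np.array([1.0, 0.0])  # all agents enter at queue 1
        visits = start @ np.linalg.inv(np.eye(2) - R)
        assert expected_sojourn(net) == pytest.approx(float(visits @ means), rel=1e-9)

    def test_scaling_arrivals_leaves_sojourn_unchanged(self, two_queue_net):
        base = expected_sojourn(two_queue_net)
        scaled = QueueNetwork(
            two_queue_net.routing,
            two_queue_net.exogenous_rates * 2.0,
            two_queue_net.services,
        )
        assert expected_sojourn(scaled) == pytest.approx(base, rel=1e-12)

    def test_no_arrivals_is_an_error(self):
        net = QueueNetwork(
            RoutingMatrix(np.zeros((1, 1))),
            np.array([1.0]),
            (ServiceSpec.exponential(1.0),),
        )
        starved = QueueNetwork(net.routing, np.array([0.0]), net.services)
        with pytest.raises(Exception):
            expected_sojourn(starved)


class TestInsensitivity:
    def test_equilibrium_depends_on_service_means_only(self, two_queue_net):
        """Swapping service families with fixed means changes nothing."""
        variants = [
            (ServiceSpec.exponential(6.0), ServiceSpec.exponential(12.0)),
            (ServiceSpec.deterministic(6.0), ServiceSpec.deterministic(12.0)),
            (ServiceSpec.lognormal(6.0, 1.3), ServiceSpec.uniform(0.0, 24.0)),
        ]
        ref = solve_traffic(two_queue_net)
        for services in variants:
            net = QueueNetwork(
                two_queue_net.routing, two_queue_net.exogenous_rates, services
            )
            sol = solve_traffic(net)
            np.testing.assert_allclose(sol.arrival_rates, ref.arrival_rates)
            np.testing.assert_allclose(sol.loads, ref.loads)
            assert expected_sojourn(net) == pytest.approx(
                expected_sojourn(two_queue_net), rel=1e-12
            )

    def test_zero_load_marginal_is_degenerate_not_an_error(self):
        model = stationary_model(
            QueueNetwork(
                RoutingMatrix(np.zeros((2, 2))),
                np.array([1.0, 0.0]),
                (ServiceSpec.exponential(2.0), ServiceSpec.exponential(3.0)),
            )
        )
        assert model.loads[1] == 0.0
        assert marginal_pmf(model, 1, 0) == 1.0
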