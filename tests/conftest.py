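import numpy as np
import pytest

from screenq.network import QueueNetwork, RoutingMatrix, ServiceSpec
from screenq.screening import ScreeningScenario, SubgroupKey, SubgroupParams
from screenq.synth import default_spec, generate_registry


@pytest.fixture
def two_queue_net() -> QueueNetwork:
    """Diagnosis -> surgery tandem: eta1=10/mo, r12=0.4, means 6 and 12 mo."""
    return QueueNetwork(
        routing=RoutingMatrix(np.array([[0.0, 0.4], [0.0, 0.0]])),
        exogenous_rates=np.array([10.0, 0.0]),
        services=(ServiceSpec.exponential(6.0), ServiceSpec.lognormal(12.0, 1.0)),
        labels=("diagnosed, awaiting surgery", "post-surgery"),
    )


@pytest.fixture
def subgroup_params() -> SubgroupParams:
    """Worked three-state example: 2y preclinical, 1y late survival, L=26.67y."""
    return SubgroupParams(
        diagnosis_rate=100.0,
        mean_early_sojourn=24.0,
        death_frac=0.1,
        screen_frac=0.3,
        progress_frac=0.6,
        mean_late_survival=12.0,
        treated_fraction=0.5,
        mean_diag_to_treatment=1.0,
        cond_life_expectancy=80.0 / 3.0,  # e*L = 20y at 75% effectiveness
    )


@pytest.fixture
def scenario() -> ScreeningScenario:
    return ScreeningScenario(detection_prob=1.0, effectiveness=0.75)


@pytest.fixture(scope="session")
def synth_bundle():
    """One reference synthetic registry with its generating truth."""
    spec = default_spec(seed=11)
    registry, truth = generate_registry(spec)
    return spec, registry, truth


@pytest.fixture
def synth_key() -> SubgroupKey:
    return SubgroupKey("pancreas", "female", "Caucasian", "60-64")
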