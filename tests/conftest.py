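import pytest

from amelonet import PipelineConfig, SimulationPlan
from amelonet.simulate import annotate_simulated, simulate_expression, simulate_variants
from amelonet.variants import run_cascade


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def plan():
    return SimulationPlan(seed=7)


@pytest.fixture(scope="session")
def variant_fixture(plan, cfg):
    """(candidates, annotation, truth) from the default plan."""
    return simulate_variants(plan, cfg)


@pytest.fixture(scope="session")
def annotated_variants(variant_fixture, cfg):
    candidates, annotation, _ = variant_fixture
    return annotate_simulated(candidates, annotation, cfg)


@pytest.fixture(scope="session")
def cascade(annotated_variants, cfg):
    return run_cascade(annotated_variants, cfg)


@pytest.fixture(scope="session")
def expression_fixture(plan):
    """(ExpressionDataset, planted labels) from the default plan."""
    return simulate_expression(plan)


@pytest.fixture(scope="session")
def network_model(expression_fixture, cfg):
    from amelonet.coexpression import build_network

    expr, _ = expression_fixture
    return build_network(expr, cfg)
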