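import numpy as np
import pytest

import milenorm as mn
from milenorm.instrument import ItemDefinition, Instrument


@pytest.fixture(scope="session")
def final_instrument():
    return mn.fixtures.load_final_instrument()


@pytest.fixture(scope="session")
def std_instrument():
    return mn.fixtures.load_standardization_instrument()


@pytest.fixture(scope="session")
def jimma_norms():
    return mn.fixtures.load_jimma_norms()


@pytest.fixture(scope="session")
def lms_reference():
    return mn.fixtures.load_synthetic_lms()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-child simulated study (chart protocol, observer + retest subsets)."""
    cfg = mn.GeneratorConfig(n_children=400, n_observer=150, n_retest=60, seed=7)
    roster, responses, truth = mn.generate_study(cfg)
    return cfg, roster, responses, truth


def make_domain(n: int, domain: str = "GM") -> tuple[ItemDefinition, ...]:
    """A bare n-item single-domain chart for scoring tests."""
    return tuple(
        ItemDefinition(item_code=f"{domain}{i}", label=f"item {i}", domain=domain,
                       chart_order=i)
        for i in range(1, n + 1)
    )


@pytest.fixture
def six_items():
    return make_domain(6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
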