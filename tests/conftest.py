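import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TRIO = """\
FAM1 F 0 0 1
FAM1 M 0 0 2
FAM1 C F M 1
"""


@pytest.fixture
def trio_path(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text(TRIO)
    return p


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic simulated study shared across tests."""
    from pedexpress.simulate import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        n_families=15, n_singletons=8, n_transcripts=200, n_controls=80, seed=11
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_413)
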