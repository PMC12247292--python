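import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from boacall.breeding import ProgramConfig, run_program
from boacall.founders import FounderConfig, simulate_founders

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def tiny_founder_config(**overrides) -> FounderConfig:
    """Small founder panel: 5 x 30 individuals, 200 SNPs on 1 Morgan."""
    defaults = dict(
        n_loci=200,
        pop_size=30,
        sequence_length_bp=2.0e5,
        seed=7,
    )
    defaults.update(overrides)
    return FounderConfig(**defaults)


def tiny_program_config(**overrides) -> ProgramConfig:
    defaults = dict(
        n_premix_generations=3,
        n_cross_rounds=3,
        n_dams=30,
        n_bulls=5,
        n_offspring=60,
        n_qtl=20,
    )
    defaults.update(overrides)
    return ProgramConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_founders():
    return simulate_founders(tiny_founder_config())


@pytest.fixture(scope="session")
def tiny_program(tiny_founders):
    rng = np.random.default_rng(11)
    return run_program(tiny_founders, tiny_program_config(), rng)
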