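import numpy as np
import pytest

from its2meta.pipeline import PipelineConfig, _simulate_inputs
from its2meta.synthetic import DivergenceSpec, build_reference_db

#: divergence bands used for recovery runs: sibling genotypes sit just
#: above 3% so that 97% clustering separates every genotype
RECOVERY_DIVERGENCE = {
    "genotype": (0.032, 0.042),
    "species": (0.06, 0.11),
    "genus": (0.18, 0.28),
}


@pytest.fixture(scope="session")
def small_db():
    return build_reference_db(seed=123, divergence_spec=DivergenceSpec(**{
        k: tuple(v) for k, v in RECOVERY_DIVERGENCE.items()
    }))


@pytest.fixture(scope="session")
def zero_error_run():
    """A small zero-error simulation shared by recovery-style tests."""
    config = PipelineConfig(
        seed=11,
        simulate={
            "divergence": RECOVERY_DIVERGENCE,
            "shared_fraction": 0.35,
            "reads_per_site": 1000,
            "error_rate": 0.0,
            "chimera_rate": 0.0,
            "offtarget_fraction": 0.0,
        },
    )
    refdb, profiles, run, group_map = _simulate_inputs(config)
    return config, refdb, profiles, run, group_map


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
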