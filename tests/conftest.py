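import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cofracnet as cfn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Seed for the default synthetic experiment exercised end-to-end.
EXPERIMENT_SEED = 7


@pytest.fixture(scope="session")
def default_experiment():
    """The default two-condition synthetic experiment with its reference set."""
    config = cfn.SyntheticConfig(seed=EXPERIMENT_SEED)
    ds_inh, ds_uninh, truth = cfn.generate_cofractionation(config)
    reference = cfn.generate_reference(
        truth,
        coverage=config.reference_coverage,
        n_decoys=config.n_decoy_complexes,
        seed=EXPERIMENT_SEED + 1000,
    )
    return config, ds_inh, ds_uninh, truth, reference


@pytest.fixture
def profile_factory():
    def make(values, protein_id="P1", condition="c"):
        return cfn.ElutionProfile(
            protein_id=protein_id, condition=condition, values=np.asarray(values, float)
        )

    return make
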