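import pytest

from mtornet.network import build_base_model, build_variant
from mtornet.synthetic import (
    SynthConfig,
    TRUTH_INPUTS,
    default_design,
    generate_phospho_table,
    generate_timecourses,
    truth_model,
)


@pytest.fixture(scope="session")
def base_extended():
    return build_base_model("extended")


@pytest.fixture(scope="session")
def base_simple():
    return build_base_model("simple")


@pytest.fixture(scope="session")
def quad_model(base_extended):
    return build_variant(base_extended, set(TRUTH_INPUTS))


@pytest.fixture(scope="session")
def truth():
    return truth_model()


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    return generate_timecourses(truth, SynthConfig(seed=11))


@pytest.fixture(scope="session")
def clean_dataset(truth):
    return generate_timecourses(
        truth, SynthConfig(seed=11, noise_cv=0.0, n_replicates=1)
    )


@pytest.fixture(scope="session")
def silac_design():
    return default_design()


@pytest.fixture(scope="session")
def phospho_table():
    return generate_phospho_table(n_sites=300, n_regulated=15, seed=7)
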