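import pytest

from mitocomp import GeneratorConfig, ancestral_order, generate_mitogenome
from mitocomp.synthetic import study_cohort_configs


@pytest.fixture(scope="session")
def default_genome():
    """One generated genome with its truth manifest (default config)."""
    return generate_mitogenome(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def cohort():
    """The nine study-condition genomes plus truths."""
    return [generate_mitogenome(cfg) for cfg in study_cohort_configs(29)]


@pytest.fixture(scope="session")
def anc():
    return ancestral_order()
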