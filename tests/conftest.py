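import pytest

from arkmito.synthetic_data import SynthConfig, gen_genome


@pytest.fixture(scope="session")
def small_genome():
    """One reduced-scale synthetic mitogenome with ground truth."""
    return gen_genome(SynthConfig.small(seed=11))


@pytest.fixture(scope="session")
def study_scale_genome():
    """A study-scale (~40 kb) synthetic mitogenome with ground truth."""
    return gen_genome(SynthConfig(seed=5))
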