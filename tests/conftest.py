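import pytest

from affopt import ETS, GeneratorConfig, gen_enhancer, gen_pbm_table


@pytest.fixture(scope="session")
def cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def pbm_table(cfg):
    """Exhaustive synthetic PBM table (decay 0.5, consensus CCGGAAGT)."""
    return gen_pbm_table(cfg)


@pytest.fixture(scope="session")
def enhancer(cfg):
    """Synthetic enhancer with six planted ETS sites; (sequence, truth)."""
    return gen_enhancer(cfg, ETS)
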