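import pytest

from oncotrace.simulate import (
    build_truth,
    default_config,
    make_panel,
    simulate_coverage,
    simulate_dna_pileups,
)
from oncotrace.somatic import PanelOfNormals


@pytest.fixture(scope="session")
def cfg():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def truth(cfg):
    return build_truth(cfg)


@pytest.fixture(scope="session")
def pileups(cfg, truth):
    return simulate_dna_pileups(cfg, truth)


@pytest.fixture(scope="session")
def coverage(cfg):
    return simulate_coverage(cfg)


@pytest.fixture(scope="session")
def panel(cfg):
    return PanelOfNormals(hits=make_panel(cfg))
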