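import numpy as np
import pytest

import gwaspeaks as g


@pytest.fixture(scope="session")
def sim_cfg():
    return g.SimConfig(master_seed=42)


@pytest.fixture(scope="session")
def genome(sim_cfg):
    return g.generate_genome(sim_cfg)


@pytest.fixture(scope="session")
def peaks_variants(sim_cfg, genome):
    sizes, _ = genome
    return g.generate_peaks_and_variants(sim_cfg, sizes)


@pytest.fixture(scope="session")
def panel(sim_cfg, peaks_variants):
    _, variants, _ = peaks_variants
    return g.generate_haplotype_panel(sim_cfg, variants)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
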