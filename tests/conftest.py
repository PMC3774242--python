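import numpy as np
import pytest

from pleiomap.simulate import (
    PanelSimConfig,
    RILSimConfig,
    simulate_accession_panel,
    simulate_ril_panel,
)


@pytest.fixture(scope="session")
def small_cross():
    """A default-sized RIL cross with the standard pleiotropic QTL set."""
    cfg = RILSimConfig(seed=11)
    gmap, panel, truth = simulate_ril_panel(cfg)
    return cfg, gmap, panel, truth


@pytest.fixture(scope="session")
def small_panel():
    """A 300-accession panel with modest genome-wide differentiation."""
    cfg = PanelSimConfig(n_accessions=300, n_genome_snps=2000, seed=7)
    panel, climate, truth = simulate_accession_panel(cfg)
    return cfg, panel, climate, truth


@pytest.fixture(scope="session")
def perfect_tag_panel():
    """A panel whose window SNPs are deterministic copies of the label."""
    cfg = PanelSimConfig(n_accessions=120, n_window_snps=5, tag_ld_r2=1.0,
                         n_genome_snps=300, seed=13)
    panel, climate, truth = simulate_accession_panel(cfg)
    return cfg, panel, climate, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
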