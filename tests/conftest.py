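import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

from gliamine.atlas_io import normalize_ln10k
from gliamine.extraction import ExtractionConfig, extract_glia
from gliamine.synthetic import SimConfig, generate_atlas, generate_multispecies

#: Master seed for the shared study-condition fixtures.
DEFAULT_ATLAS_SEED = 1


@pytest.fixture(scope="session")
def small_atlas():
    """A cheap atlas for unit tests (not the study condition)."""
    cfg = SimConfig(seed=7, n_cells=2_000, n_genes=800)
    counts, cells = generate_atlas(cfg)
    return cfg, counts, cells


@pytest.fixture(scope="session")
def default_atlas():
    """The default study condition: 20,000 cells, 0.5% glia, fixed seed."""
    cfg = SimConfig(seed=DEFAULT_ATLAS_SEED)
    counts, cells = generate_atlas(cfg)
    return cfg, counts, cells


@pytest.fixture(scope="session")
def default_normalized(default_atlas):
    _, counts, _ = default_atlas
    return normalize_ln10k(counts)


@pytest.fixture(scope="session")
def default_extraction(default_atlas, default_normalized):
    """Full extraction chain on the default study condition."""
    _, counts, cells = default_atlas
    return extract_glia(counts, cells, ExtractionConfig(seed=0),
                        norm=default_normalized)


@pytest.fixture(scope="session")
def glia_rich_bundle():
    """Small glia-rich multispecies data without hybrids.

    Used for cross-species consensus unit tests where rarity is irrelevant:
    600 glia per species give the rank-sum tests full power and the planted
    structure is clean (no intermediate cells).
    """
    cfg = SimConfig(seed=3, n_cells=3_000, glial_fraction=0.2,
                    hybrid_fraction=0.0, species=("mouse", "lemur", "human"))
    per_species, orthologs = generate_multispecies(cfg)
    return cfg, per_species, orthologs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
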