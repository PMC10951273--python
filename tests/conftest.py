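import numpy as np
import pandas as pd
import pytest

from ssbreed import (
    GeneticMap,
    Pedigree,
    SimConfig,
    TraitArchitecture,
    simulate_breeding_program,
)
from ssbreed._rng import substream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_map():
    return GeneticMap.uniform(12, n_chrom=3, length_cm=90.0)


@pytest.fixture
def toy_pedigree():
    """Founders A,B; C = A x B; D = A x B (full sib of C); E = C x D."""
    return Pedigree.from_frame(pd.DataFrame({
        "id": ["A", "B", "C", "D", "E"],
        "sire": ["0", "0", "A", "A", "C"],
        "dam": ["0", "0", "B", "B", "D"],
        "birth_year": [1900, 1900, 1920, 1921, 1940],
    }))


@pytest.fixture(scope="session")
def small_program():
    """A compact selected program reused across tests (deterministic)."""
    cfg = SimConfig(n_founders=30, n_markers=80, founder_year=1900, end_year=2000,
                    cp_year=1950, crosses_per_year=2, progeny_per_cross=3,
                    genotyped_fraction=0.6, missing_rate=0.02, seed=7)
    gmap = GeneticMap.uniform(cfg.n_markers, n_chrom=4)
    arch = TraitArchitecture.random(gmap, n_traits=2, trait_corr=0.5,
                                    rng=substream(7, "architecture"))
    return simulate_breeding_program(cfg, gmap, arch)
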