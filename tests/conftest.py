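import numpy as np
import pandas as pd
import pytest

from lincsynteny.neighborhood import GenomeAnnotation
from lincsynteny.phylo import Phylogeny
from lincsynteny.simulate import SimulationConfig, simulate_all, simulate_tree


@pytest.fixture(scope="session")
def small_tree() -> Phylogeny:
    return simulate_tree(8, seed=5)


@pytest.fixture(scope="session")
def tiny_world():
    """A compact sequence-bearing world reused by slower integration tests."""
    cfg = SimulationConfig(
        n_species=5,
        n_neuro_linc=10,
        n_other_linc=6,
        median_distance_bp=800,
        distance_sigma=0.6,
        gene_length=300,
        linc_length=300,
        loss_rate_high=0.4,
        loss_rate_low=1.2,
        seed=11,
    )
    return simulate_all(cfg)


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """One chromosome: coding genes at [100,200) and [500,600), lincRNA at
    [300,400)."""
    return GenomeAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["geneA", "linc1", "geneB"],
                "chrom": ["chr1"] * 3,
                "start": [100, 300, 500],
                "end": [200, 400, 600],
                "strand": ["+"] * 3,
                "biotype": ["protein_coding", "lincRNA", "protein_coding"],
            }
        ),
        species="human",
    )
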