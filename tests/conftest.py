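import numpy as np
import pandas as pd
import pytest

from tagwinnow.simulate import FragmentDist, SimulationParams, simulate_catalogue


@pytest.fixture
def small_params():
    """A small but fully featured synthetic study (3 fragments/transcript)."""
    return SimulationParams(
        n_transcripts=60,
        fragments_per_transcript=FragmentDist("constant", 3),
        depth_per_treatment=30_000,
        seed=7,
    )


@pytest.fixture
def small_catalogue(small_params):
    return simulate_catalogue(small_params)


@pytest.fixture
def tiny_annotation():
    """Three contigs: two share an accession, one is unannotated."""
    return pd.DataFrame(
        {
            "contig_id": ["c1", "c2", "c3"],
            "length_bp": [200, 350, 120],
            "accession": ["ACC_A", "ACC_A", None],
            "gene_name": ["geneA", "geneA", ""],
            "species": ["Heliothis virescens"] * 3,
            "evalue": [1e-30, 1e-12, 1e-8],
            "pct_coverage": [80, 55, 40],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
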