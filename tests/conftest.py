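import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from xcoex import (
    CommunityConfig,
    CountMatrix,
    GeneAnnotation,
    PlantedInteraction,
    generate_community,
    generate_module_db,
)


@pytest.fixture(scope="session")
def small_community():
    """3 taxa × 60 genes × 24 samples, no planted structure."""
    cfg = CommunityConfig(n_taxa=3, genes_per_taxon=60, n_samples=24, seed=7)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def planted_community():
    """Community with one planted producer/consumer pair at coupling 0.9."""
    pi = PlantedInteraction("T01", "prod", "T02", "cons", sign=1, coupling=0.9)
    cfg = CommunityConfig(
        n_taxa=4, genes_per_taxon=120, n_samples=30,
        planted_interactions=(pi,), seed=11,
    )
    cm, truth = generate_community(cfg)
    db, gene_kos, planted_modules = generate_module_db(
        12, seed=11, community=cm, truth=truth
    )
    return cm, truth, db, gene_kos, planted_modules


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        np.arange(6).reshape(3, 2),
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=pd.Index(["s1", "s2"], name="sample_id"),
    )
    taxon = pd.Series(["A", "A", "B"], index=counts.index, name="taxon")
    return CountMatrix(counts=counts, gene_taxon=taxon)


def make_annotations(starts_ends, taxon="T01", contig="ctg1"):
    """Helper: GeneAnnotation dict from a list of (gene_id, start, end)."""
    return {
        g: GeneAnnotation(gene_id=g, taxon=taxon, contig=contig, start=s, end=e)
        for g, s, e in starts_ends
    }
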