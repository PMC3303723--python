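import pytest

from esrscan.phylo_clusters import (
    ALL_SPECIES,
    DEFAULT_CLUSTER_CONFIG,
    build_cluster_set,
)
from esrscan.synthetic_fixtures import AlignmentSimSpec, PlantedMotif, make_alignment


@pytest.fixture(scope="session")
def cluster_set():
    return build_cluster_set(DEFAULT_CLUSTER_CONFIG)


@pytest.fixture(scope="session")
def all_cluster(cluster_set):
    return cluster_set["all"]


@pytest.fixture
def planted_alignment():
    """15-species alignment, 0.5 background, fully conserved hexamer at 27."""
    spec = AlignmentSimSpec(
        species=tuple(ALL_SPECIES),
        length=60,
        seed=42,
        match_prob=0.5,
        planted=(PlantedMotif(offset=27, length=6),),
    )
    return make_alignment(spec)


@pytest.fixture
def conserved_alignment():
    """Fully conserved 15-species alignment of length 30."""
    spec = AlignmentSimSpec(
        species=tuple(ALL_SPECIES), length=30, seed=1, match_prob=1.0
    )
    aln, _ = make_alignment(spec)
    return aln
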