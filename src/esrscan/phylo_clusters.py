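"""Phylogenetic clusters, proximities and conservation thresholds.

Species are grouped into overlapping clusters of increasing phylogenetic
depth.  For a cluster with tree distance ``s`` (expected substitutions per
site), the proximity ``q = exp(-s)`` approximates the probability that a
neutral base has not mutated across that distance.  The per-cluster
conservation threshold is ``q+ = q + a``, where ``a = 1 - q(reference)`` is
the "conservation deficit" of the closest-species reference cluster; a
sliding-window conservation score must reach ``q+`` before a window can be
called a conservation spike.  The reference cluster itself is given an
override threshold of 1 (its species are so close that only perfect
conservation is meaningful).

``q`` and ``q+`` are carried at full floating precision and rounded to six
decimals only for display; rounding before the ``q + a`` sum shifts the
sixth decimal for some clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

__all__ = [
    "PhyloCluster",
    "ClusterSet",
    "parse_tree",
    "cluster_distance",
    "proximity",
    "build_cluster_set",
    "load_cluster_config",
    "DEFAULT_CLUSTER_CONFIG",
    "DEFAULT_REFERENCE_SPECIES",
]

# UCSC-style assembly names for the 15 insect species: the 12 Drosophila
# genomes plus the mosquito, honeybee and red flour beetle outgroups.
MELANOGASTER_SUBGROUP: tuple[str, ...] = (
    "dm2",
    "droSim1",
    "droSec1",
    "droYak2",
    "droEre2",
)
DROSOPHILA_12: tuple[str, ...] = MELANOGASTER_SUBGROUP + (
    "droAna3",
    "dp4",
    "droPer1",
    "droWil1",
    "droVir3",
    "droMoj3",
    "droGri2",
)
ALL_SPECIES: tuple[str, ...] = DROSOPHILA_12 + ("anoGam1", "apiMel2", "triCas2")

DEFAULT_REFERENCE_SPECIES = "dm2"

# Default cluster definitions.  Tree distances are supplied directly so the
# thresholds do not depend on any branch-length aggregation convention.
DEFAULT_CLUSTER_CONFIG: list[dict] = [
    {"name": "dro1", "species": list(MELANOGASTER_SUBGROUP), "s": 0.039669,
     "override_threshold": 1.0},
    {"name": "dro2", "species": list(DROSOPHILA_12), "s": 0.21},
    {"name": "dro_anoGam", "species": list(DROSOPHILA_12 + ("anoGam1",)),
     "s": 0.191225384},
    {"name": "dro_apiMel", "species": list(DROSOPHILA_12 + ("apiMel2",)),
     "s": 0.231922},
    {"name": "dro_triCas", "species": list(DROSOPHILA_12 + ("triCas2",)),
     "s": 0.324132615},
    {"name": "all", "species": list(ALL_SPECIES), "s": 0.3252756},
]


@dataclass(frozen=True)
class PhyloCluster:
    """A named species group with tree distance s, proximity q and threshold q+."""

    name: str
    species: tuple[str, ...]
    s: float
    q: float
    q_plus: float
    override_threshold: float | None = None

    @property
    def threshold(self) -> float:
        """The effective spike threshold (override wins over q+)."""
        return self.q_plus if self.override_threshold is None else self.override_threshold

    @property
    def size(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[PhyloCluster, ...]
    a: float
    reference_cluster: str

    def __getitem__(self, name: str) -> PhyloCluster:
        for c in self.clusters:
            if c.name == name:
                return c
        raise KeyError(name)

    def __iter__(self):
        return iter(self.clusters)

    def table(self) -> pd.DataFrame:
        """Per-cluster report: tree distance, q and q+ rounded to 6 decimals."""
        return pd.DataFrame(
            [
                {
                    "cluster": c.name,
                    "s": c.s,
                    "q": round(c.q, 6),
                    "q_plus": round(c.threshold, 6),
                }
                for c in self.clusters
            ]
        )


def parse_tree(text: str) -> dendropy.Tree:
    """Parse a Newick tree, requiring a branch length on every non-root edge."""
    try:
        # read as rooted so the written topology and branch lengths are kept
        # verbatim (unrooted handling would merge the root bifurcation)
        tree = dendropy.Tree.get(data=text, schema="newick", rooting="default-rooted")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick tree: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge carries no length
            continue
        if edge.length is None:
            head = edge.head_node
            label = head.taxon.label if head.taxon else "internal node"
            raise ValueError(f"missing branch length on edge leading to {label}")
    return tree


def cluster_distance(
    tree: dendropy.Tree,
    species: Iterable[str],
    mode: str = "mean_mrca_to_tip",
    supplied: float | None = None,
) -> float:
    """Tree distance s for a species cluster.

    ``mean_mrca_to_tip`` / ``max_mrca_to_tip`` aggregate the path lengths
    from the cluster's most recent common ancestor to each member tip;
    ``supplied`` returns an externally given distance unchanged.
    """
    if mode == "supplied":
        if supplied is None:
            raise ValueError("mode='supplied' requires an explicit distance")
        return float(supplied)
    species = list(species)
    labels = {t.label for t in tree.taxon_namespace}
    unknown = sorted(set(species) - labels)
    if unknown:
        raise ValueError(f"species not in tree: {', '.join(unknown)}")
    mrca = tree.mrca(taxon_labels=species)
    dists = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label not in species:
            continue
        d, node = 0.0, leaf
        while node is not mrca:
            d += node.edge.length or 0.0
            node = node.parent_node
        dists.append(d)
    if mode == "mean_mrca_to_tip":
        return sum(dists) / len(dists)
    if mode == "max_mrca_to_tip":
        return max(dists)
    raise ValueError(f"unknown distance mode {mode!r}")


def proximity(s: float) -> float:
    """Proximity q = exp(-s): P(a neutral base unchanged over distance s)."""
    if s < 0:
        raise ValueError(f"tree distance must be >= 0, got {s}")
    return math.exp(-s)


def build_cluster_set(
    cluster_config: Sequence[Mapping],
    tree: dendropy.Tree | None = None,
    reference: str = "dro1",
    distance_mode: str = "supplied",
) -> ClusterSet:
    """Compute q and q+ for every configured cluster.

    Each config entry carries ``name``, ``species`` and either a supplied
    tree distance ``s`` or (with a tree and a non-supplied ``distance_mode``)
    the distance is derived from the tree.  The offset ``a`` is
    ``1 - q(reference)``; every threshold is ``q + a`` at full precision
    unless the entry sets ``override_threshold``.
    """
    by_name = {}
    distances: dict[str, float] = {}
    for entry in cluster_config:
        name = entry["name"]
        spp = tuple(entry["species"])
        if not spp:
            raise ValueError(f"cluster {name!r} has an empty species set")
        by_name[name] = entry
        if distance_mode == "supplied":
            if "s" not in entry:
                raise ValueError(f"cluster {name!r} has no supplied tree distance")
            distances[name] = float(entry["s"])
        else:
            if tree is None:
                raise ValueError("a tree is required when distances are not supplied")
            distances[name] = cluster_distance(tree, spp, mode=distance_mode)
    if reference not in by_name:
        raise ValueError(f"reference cluster {reference!r} not in configuration")

    a = 1.0 - proximity(distances[reference])
    clusters = []
    for entry in cluster_config:
        name = entry["name"]
        q = proximity(distances[name])
        clusters.append(
            PhyloCluster(
                name=name,
                species=tuple(entry["species"]),
                s=distances[name],
                q=q,
                q_plus=q + a,
                override_threshold=entry.get("override_threshold"),
            )
        )
    return ClusterSet(clusters=tuple(clusters), a=a, reference_cluster=reference)


def load_cluster_config(text: str) -> list[dict]:
    """Load a YAML cluster configuration (list of cluster entries)."""
    config = yaml.safe_load(text)
    if not isinstance(config, list):
        raise ValueError("cluster configuration must be a list of cluster entries")
    return config
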