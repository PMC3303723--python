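"""Seeded synthetic inputs with known ground truth.

Two generators drive the test suite and power studies:

* random splicing graphs with genomic-order-respecting edges, paired with
  cassette-pair statuses computed by an independent brute-force oracle
  (exhaustive source-to-sink path enumeration plus literal re-application
  of the four exclusion rules);
* synthetic exon alignments in which every non-reference residue matches
  the reference with a per-column probability — uniform background noise
  with optional planted fully (or partially) conserved runs, mimicking a
  regulatory motif embedded in a diverged exon.

Mismatch bases are drawn uniformly from the three non-reference bases; no
indels are simulated by default (columns with gaps are penalised or
dropped downstream anyway), but gaps can be injected for format tests.
All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .alignment_io import ExonAlignment
from .splice_graph import ExonNode, SplicingGraph

__all__ = [
    "GraphSimSpec",
    "AlignmentSimSpec",
    "PlantedMotif",
    "make_graph",
    "brute_force_statuses",
    "make_alignment",
    "alignment_to_maf",
    "ladder_newick",
    "cluster_config_yaml",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# splicing graphs


@dataclass(frozen=True)
class GraphSimSpec:
    n_nodes: int
    seed: int
    cassette_fraction: float = 0.6
    edge_prob: float = 0.35
    overlap_prob: float = 0.15
    gene_id: str = "simgene"
    chrom: str = "chr1"
    node_prefix: str = "n"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")


def make_graph(spec: GraphSimSpec) -> tuple[SplicingGraph, dict[tuple[str, str], str]]:
    """Random order-respecting DAG plus oracle statuses for cassette pairs."""
    rng = np.random.default_rng(spec.seed)
    graph = SplicingGraph(gene_id=spec.gene_id)
    pos = 0
    prev: ExonNode | None = None
    for i in range(spec.n_nodes):
        if prev is not None and rng.random() < spec.overlap_prob:
            # overlap the previous exon but shift start/end so lengths differ
            start = prev.start + int(rng.integers(1, max(prev.length, 2)))
            end = start + int(rng.integers(20, 200))
        else:
            start = pos + int(rng.integers(10, 100))
            end = start + int(rng.integers(20, 200))
        node = ExonNode(
            node_id=f"{spec.node_prefix}{i:02d}",
            chrom=spec.chrom,
            start=start,
            end=end,
            strand="+",
            is_cassette=bool(rng.random() < spec.cassette_fraction),
        )
        graph.add_node(node)
        pos = max(pos, end)
        prev = node
    ids = sorted(graph.nodes)
    for a, b in itertools.combinations(ids, 2):
        na, nb = graph.nodes[a], graph.nodes[b]
        if na.end <= nb.start and rng.random() < spec.edge_prob:
            graph.add_edge(a, b)
    graph.validate()
    return graph, brute_force_statuses(graph)


def brute_force_statuses(graph: SplicingGraph) -> dict[tuple[str, str], str]:
    """Oracle: statuses via exhaustive path enumeration + literal rules.

    Connectivity is decided by co-occurrence on some source-to-sink path of
    the DAG (enumerated exhaustively, so only suitable for small graphs);
    the overlap, rule-3 and rule-4 logic is re-stated here from scratch.
    """
    cassettes = sorted(n.node_id for n in graph.nodes.values() if n.is_cassette)

    def ivl_overlap(x: str, y: str) -> bool:
        nx_, ny = graph.nodes[x], graph.nodes[y]
        if nx_.chrom != ny.chrom or nx_.strand != ny.strand:
            return False
        return max(nx_.start, ny.start) < min(nx_.end, ny.end)

    status: dict[tuple[str, str], str] = {}
    for a, b in itertools.combinations(cassettes, 2):
        status[(a, b)] = "o" if ivl_overlap(a, b) else "m"

    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    sources = [v for v in g if g.in_degree(v) == 0]
    sinks = [v for v in g if g.out_degree(v) == 0]
    on_same_path: set[tuple[str, str]] = set()
    for s in sources:
        for t in sinks:
            if s == t:
                continue
            for path in nx.all_simple_paths(g, s, t):
                cass_on_path = [v for v in path if graph.nodes[v].is_cassette]
                for a, b in itertools.combinations(sorted(cass_on_path), 2):
                    on_same_path.add((a, b))
    for pair in on_same_path:
        if status.get(pair) == "m":
            status[pair] = "c"

    # rule 3, literally: an m-pair (a, b) is excluded when a overlaps some
    # exon c for which (c, b) was marked connected
    c_pairs = [p for p, s in status.items() if s == "c"]
    for pair in [p for p, s in status.items() if s == "m"]:
        for cp in c_pairs:
            shared = set(pair) & set(cp)
            if len(shared) != 1:
                continue
            (b,) = shared
            a = next(x for x in pair if x != b)
            c = next(x for x in cp if x != b)
            if ivl_overlap(a, c):
                status[pair] = "t"
                break

    # rule 4, literally on the snapshot of surviving candidates
    m_snapshot = [p for p, s in status.items() if s == "m"]
    for p1, p2 in itertools.combinations(m_snapshot, 2):
        shared = set(p1) & set(p2)
        if len(shared) != 1:
            continue
        (b,) = shared
        a = next(x for x in p1 if x != b)
        c = next(x for x in p2 if x != b)
        if not ivl_overlap(a, c):
            continue
        la = graph.nodes[a].end - graph.nodes[a].start
        lc = graph.nodes[c].end - graph.nodes[c].start
        if (la, a) < (lc, c):
            status[p1] = "f"
        else:
            status[p2] = "f"

    return status


# ---------------------------------------------------------------------------
# exon alignments


@dataclass(frozen=True)
class PlantedMotif:
    offset: int
    length: int
    match_prob: float = 1.0


@dataclass(frozen=True)
class AlignmentSimSpec:
    species: tuple[str, ...]
    length: int
    seed: int
    match_prob: float | Mapping[str, float] = 0.5
    planted: tuple[PlantedMotif, ...] = ()
    gap_prob: float = 0.0
    gene_id: str = "simgene"
    exon_id: str = "simexon"

    def __post_init__(self) -> None:
        for m in self.planted:
            if not (0 <= m.offset and m.offset + m.length <= self.length):
                raise ValueError(f"planted motif {m} outside exon [0, {self.length})")
            if not 0 <= m.match_prob <= 1:
                raise ValueError("planted match probability must lie in [0, 1]")


def make_alignment(spec: AlignmentSimSpec) -> tuple[ExonAlignment, list[PlantedMotif]]:
    """Simulate a reference-anchored exon alignment with planted motifs.

    The reference row (first species) is uniform over ACGT; every other
    residue equals the reference with its column's match probability, else
    a uniformly drawn different base.  Planted intervals override the
    background probability.  Returns the alignment plus the plant truth.
    """
    rng = np.random.default_rng(spec.seed)
    ref_species = spec.species[0]
    L = spec.length
    ref = rng.choice(_BASES, size=L)

    def prob_for(sp: str) -> np.ndarray:
        base = (
            spec.match_prob[sp]
            if isinstance(spec.match_prob, Mapping)
            else spec.match_prob
        )
        p = np.full(L, float(base))
        for m in spec.planted:
            p[m.offset : m.offset + m.length] = m.match_prob
        return p

    rows = {ref_species: "".join(ref)}
    for sp in spec.species[1:]:
        p = prob_for(sp)
        match = rng.random(L) < p
        # uniformly one of the three non-reference bases where mismatching
        shift = rng.integers(1, 4, size=L)
        ref_idx = np.searchsorted(_BASES, ref)
        alt = _BASES[(ref_idx + shift) % 4]
        residues = np.where(match, ref, alt)
        if spec.gap_prob > 0:
            residues = np.where(rng.random(L) < spec.gap_prob, "-", residues)
        rows[sp] = "".join(residues)
    aln = ExonAlignment(
        gene_id=spec.gene_id,
        exon_id=spec.exon_id,
        reference_species=ref_species,
        rows=rows,
        ref_coords=np.arange(L),
    )
    return aln, list(spec.planted)


def alignment_to_maf(
    aln: ExonAlignment, chrom: str = "chr1", ref_start: int = 0
) -> str:
    """Serialize an exon alignment as a single MAF block (reference first)."""
    lines = ["##maf version=1", "a score=0.000000"]
    order = [aln.reference_species] + [
        sp for sp in aln.species if sp != aln.reference_species
    ]
    for sp in order:
        seq = aln.rows[sp]
        size = len(seq) - seq.count("-")
        src = f"{sp}.{chrom}" if sp == aln.reference_species else f"{sp}.scaf1"
        start = ref_start if sp == aln.reference_species else 0
        src_size = start + size + 1000
        lines.append(f"s {src} {start} {size} + {src_size} {seq}")
    return "\n".join(lines) + "\n\n"


def ladder_newick(species: Sequence[str], branch_length: float = 0.05) -> str:
    """A caterpillar tree over the given species with uniform branch lengths."""
    if len(species) < 2:
        raise ValueError("need at least two species")
    bl = f":{branch_length}"
    tree = f"({species[0]}{bl},{species[1]}{bl})"
    for sp in species[2:]:
        tree = f"({tree}:{branch_length},{sp}{bl})"
    return tree + ";"


def cluster_config_yaml(config: Sequence[Mapping]) -> str:
    """Cluster configuration serialized as YAML (round-trips through loader)."""
    return yaml.safe_dump([dict(entry) for entry in config], sort_keys=False)
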