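"""Splicing graphs and mutually exclusive (ME) exon detection.

A splicing graph summarises all EST-observed transcripts of one gene as a
directed acyclic graph: nodes are exons (merged when they share genomic
start and end), edges are observed exon-to-exon junctions.  Cassette exons
(present in some transcripts, absent from others) are the candidates for
mutually exclusive splicing: an ME pair is two cassette exons that never
co-occur in a transcript and for which the EST evidence suggests one is
chosen instead of the other.

Every unordered cassette pair receives exactly one status flag:

``o``
    the exons overlap genomically (rule 1);
``c``
    one exon is reachable from the other, i.e. they can co-occur on a
    transcript path (rule 2);
``t``
    the pair is excluded because one of its exons overlaps an exon that is
    connected to the other (rule 3);
``f``
    the pair is excluded in favour of an overlapping alternative pair whose
    non-shared exon is longer (rule 4);
``m``
    mutually exclusive — no rule excluded the pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable
from xml.etree import ElementTree

import networkx as nx

__all__ = [
    "ExonNode",
    "SplicingGraph",
    "MePairResult",
    "GraphValidationError",
    "GraphParseError",
    "parse_splicing_graph",
    "write_plain",
    "overlaps",
    "connected_cassette_pairs",
    "identify_me_pairs",
    "me_pairs_table",
]

_VALID_STATUS = frozenset("moctf")


class GraphParseError(ValueError):
    """Raised when a splicing-graph document cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when a parsed document violates splicing-graph invariants."""


@dataclass(frozen=True)
class ExonNode:
    """One exon: a genomic interval with 0-based half-open coordinates."""

    node_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_cassette: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GraphValidationError(
                f"exon {self.node_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GraphValidationError(
                f"exon {self.node_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GraphValidationError(
                f"exon {self.node_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SplicingGraph:
    """A gene's exons plus the directed exon-to-exon junctions."""

    gene_id: str
    nodes: dict[str, ExonNode] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def add_node(self, node: ExonNode) -> None:
        if node.node_id in self.nodes:
            raise GraphValidationError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, src: str, dst: str) -> None:
        self.edges.append((src, dst))

    def cassette_ids(self) -> list[str]:
        return sorted(n.node_id for n in self.nodes.values() if n.is_cassette)

    def successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for src, dst in self.edges:
            adj[src].append(dst)
        return adj

    def validate(self) -> None:
        """Check edge endpoints, acyclicity and transcription order."""
        for src, dst in self.edges:
            for nid in (src, dst):
                if nid not in self.nodes:
                    raise GraphValidationError(
                        f"gene {self.gene_id}: edge ({src}, {dst}) references "
                        f"unknown node {nid!r}"
                    )
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphValidationError(
                f"gene {self.gene_id}: edge set contains a cycle: {cycle}"
            )
        for src, dst in self.edges:
            a, b = self.nodes[src], self.nodes[dst]
            # transcription order: on '+' the upstream exon ends before the
            # downstream one starts; mirrored on '-'
            ordered = a.end <= b.start if a.strand == "+" else b.end <= a.start
            if not ordered:
                raise GraphValidationError(
                    f"gene {self.gene_id}: edge ({src}, {dst}) violates genomic "
                    f"order on the transcribed strand"
                )


@dataclass(frozen=True)
class MePairResult:
    """One flagged cassette exon pair; ``exon_a`` sorts before ``exon_b``."""

    exon_a: str
    exon_b: str
    status: str

    def __post_init__(self) -> None:
        if self.exon_a == self.exon_b:
            raise ValueError("a pair must consist of two distinct exons")
        if self.exon_a > self.exon_b:
            raise ValueError("pair must be canonicalized (exon_a < exon_b)")
        if self.status not in _VALID_STATUS:
            raise ValueError(f"invalid status {self.status!r}")


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# parsing


def parse_splicing_graph(text: str, fmt: str = "plain") -> SplicingGraph:
    """Parse a splicing-graph document.

    ``fmt="plain"`` is this package's tab-separated format (GENE / NODE /
    EDGE records, coordinates 0-based half-open).  ``fmt="dedb-xml"`` is a
    DEDB-style XML dialect with ``<node>`` and ``<connection>`` elements,
    declared with 1-based inclusive coordinates and converted on parse.
    The parsed graph is validated (edge endpoints, acyclicity, order).
    """
    if fmt == "plain":
        graph = _parse_plain(text)
    elif fmt == "dedb-xml":
        graph = _parse_dedb_xml(text)
    else:
        raise ValueError(f"unknown splicing-graph format {fmt!r}")
    graph.validate()
    return graph


def _parse_plain(text: str) -> SplicingGraph:
    graph: SplicingGraph | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag == "GENE":
                graph = SplicingGraph(gene_id=fields[1])
            elif tag == "NODE":
                if graph is None:
                    raise GraphParseError("NODE record before GENE record")
                _, nid, chrom, start, end, strand, cassette, *rest = fields
                graph.add_node(
                    ExonNode(
                        node_id=nid,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        is_cassette=cassette == "1",
                        sequence=rest[0] if rest and rest[0] else None,
                    )
                )
            elif tag == "EDGE":
                if graph is None:
                    raise GraphParseError("EDGE record before GENE record")
                graph.add_edge(fields[1], fields[2])
            else:
                raise GraphParseError(f"unknown record type {tag!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, (GraphParseError, GraphValidationError)):
                raise type(exc)(f"line {lineno}: {exc}") from None
            raise GraphParseError(f"line {lineno}: malformed record: {raw!r}") from exc
    if graph is None:
        raise GraphParseError("document contains no GENE record")
    return graph


def _parse_dedb_xml(text: str) -> SplicingGraph:
    try:
        root = ElementTree.fromstring(text)
    except ElementTree.ParseError as exc:
        raise GraphParseError(f"malformed XML: {exc}") from exc
    if root.tag != "gene":
        raise GraphParseError(f"expected root element <gene>, found <{root.tag}>")
    graph = SplicingGraph(gene_id=root.attrib.get("id", ""))
    for elem in root:
        if elem.tag == "node":
            try:
                start1 = int(elem.attrib["start"])
                end1 = int(elem.attrib["end"])
                graph.add_node(
                    ExonNode(
                        node_id=elem.attrib["id"],
                        chrom=elem.attrib.get("chrom", ""),
                        start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                        end=end1,
                        strand=elem.attrib.get("strand", "+"),
                        is_cassette=elem.attrib.get("type") == "cassette_exon",
                        sequence=elem.attrib.get("sequence") or None,
                    )
                )
            except KeyError as exc:
                raise GraphParseError(f"<node> missing attribute {exc}") from None
        elif elem.tag == "connection":
            try:
                graph.add_edge(elem.attrib["from"], elem.attrib["to"])
            except KeyError as exc:
                raise GraphParseError(f"<connection> missing attribute {exc}") from None
        else:
            raise GraphParseError(f"unexpected element <{elem.tag}>")
    return graph


def write_plain(graph: SplicingGraph) -> str:
    """Serialize a graph in the plain tab-separated format (round-trips)."""
    lines = [f"GENE\t{graph.gene_id}"]
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        rec = [
            "NODE",
            n.node_id,
            n.chrom,
            str(n.start),
            str(n.end),
            n.strand,
            "1" if n.is_cassette else "0",
        ]
        if n.sequence is not None:
            rec.append(n.sequence)
        lines.append("\t".join(rec))
    for src, dst in sorted(graph.edges):
        lines.append(f"EDGE\t{src}\t{dst}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ME-pair algorithm


def overlaps(a: ExonNode, b: ExonNode) -> bool:
    """True iff the half-open genomic intervals intersect (same chrom/strand)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    return a.start < b.end and b.start < a.end


def connected_cassette_pairs(graph: SplicingGraph) -> set[tuple[str, str]]:
    """Cassette pairs where one exon is reachable from the other (DFS)."""
    adj = graph.successors()
    cassettes = graph.cassette_ids()
    cassette_set = set(cassettes)
    connected: set[tuple[str, str]] = set()
    for a in cassettes:
        # iterative DFS from a; any cassette encountered downstream is
        # connected to a (covers both directions once run from every cassette)
        stack = list(adj[a])
        seen: set[str] = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            if nid in cassette_set:
                connected.add(_canon(a, nid))
            stack.extend(adj[nid])
    return connected


def identify_me_pairs(graph: SplicingGraph) -> list[MePairResult]:
    """Flag every unordered cassette pair by the four exclusion rules.

    Rules are applied in order: overlap (``o``), connectivity (``c``),
    overlap-with-a-connected-exon (``t``), competition between two candidate
    pairs sharing an exon (``f``); surviving pairs are mutually exclusive
    (``m``).  Rules 3 and 4 are evaluated against the status snapshot left
    by the previous rule, which makes the outcome independent of pair
    iteration order.  Rule 4 demotes, among two candidate pairs sharing one
    exon whose non-shared exons overlap, the pair whose non-shared exon is
    shorter (ties broken toward the lexicographically smaller node id).
    """
    cassettes = graph.cassette_ids()
    if len(cassettes) < 2:
        return []
    status: dict[tuple[str, str], str] = {}

    # rule 1: overlap, else candidate
    for a, b in itertools.combinations(cassettes, 2):
        pair = _canon(a, b)
        status[pair] = "o" if overlaps(graph.nodes[a], graph.nodes[b]) else "m"

    # rule 2: connected pairs
    for pair in connected_cassette_pairs(graph):
        if status[pair] == "m":
            status[pair] = "c"

    # rule 3: (a,b) is excluded if a overlaps some c with (c,b) connected
    c_pairs = [p for p, s in status.items() if s == "c"]
    for pair in sorted(p for p, s in status.items() if s == "m"):
        if _rule3_hit(graph, pair, c_pairs):
            status[pair] = "t"

    # rule 4: among surviving candidate pairs sharing an exon with
    # overlapping non-shared exons, keep only the longer-exon pair
    m_pairs = sorted(p for p, s in status.items() if s == "m")
    for pair_ab, pair_cb in itertools.combinations(m_pairs, 2):
        shared = set(pair_ab) & set(pair_cb)
        if len(shared) != 1:
            continue
        (b,) = shared
        a = pair_ab[0] if pair_ab[1] == b else pair_ab[1]
        c = pair_cb[0] if pair_cb[1] == b else pair_cb[1]
        ea, ec = graph.nodes[a], graph.nodes[c]
        if not overlaps(ea, ec):
            continue
        if (ea.length, a) < (ec.length, c):
            status[pair_ab] = "f"
        else:
            status[pair_cb] = "f"

    return [MePairResult(a, b, s) for (a, b), s in sorted(status.items())]


def _rule3_hit(
    graph: SplicingGraph,
    pair: tuple[str, str],
    c_pairs: Iterable[tuple[str, str]],
) -> bool:
    for cp in c_pairs:
        shared = set(pair) & set(cp)
        if len(shared) != 1:
            continue
        (b,) = shared
        a = pair[0] if pair[1] == b else pair[1]
        c = cp[0] if cp[1] == b else cp[1]
        if overlaps(graph.nodes[a], graph.nodes[c]):
            return True
    return False


def me_pairs_table(graphs: Iterable[SplicingGraph]):
    """All cassette-pair statuses as a tidy table (gene_id, exon_a, exon_b, status)."""
    import pandas as pd

    rows = [
        {"gene_id": g.gene_id, "exon_a": p.exon_a, "exon_b": p.exon_b, "status": p.status}
        for g in graphs
        for p in identify_me_pairs(g)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "exon_a", "exon_b", "status"])
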