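"""Collation of significant spike motifs and differential ME-pair reporting.

Spikes surviving the scan are binned into significance tiers (uncorrected
p < 0.01 on either or both flanks; FDR-adjusted q < 0.05 on either or
both), ME exon pairs are checked for motifs present in one exon but absent
from its partner, and motif sets can be intersected with external splicing
regulator word lists (exact string membership).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .spike_scan import SpikeTest
from .splice_graph import MePairResult

__all__ = [
    "MotifRecord",
    "TIERS",
    "assign_tiers",
    "tier_counts",
    "differential_me_motifs",
    "match_external",
    "load_word_list",
]

TIERS = ("both_p01", "either_p01", "fdr05_either", "fdr05_both")


@dataclass(frozen=True)
class MotifRecord:
    motif: str
    gene_id: str
    exon_id: str
    offset: int
    cluster: str
    p_left: float | None
    p_right: float | None
    q_left: float | None
    q_right: float | None
    tiers: frozenset[str]


def _tiers_for(
    p_left, p_right, q_left, q_right, p01: float, fdr_alpha: float
) -> frozenset[str]:
    tiers = set()
    lp = p_left is not None and p_left < p01
    rp = p_right is not None and p_right < p01
    lq = q_left is not None and q_left < fdr_alpha
    rq = q_right is not None and q_right < fdr_alpha
    if lp and rp:
        tiers.add("both_p01")
    if lp or rp:
        tiers.add("either_p01")
    if lq or rq:
        tiers.add("fdr05_either")
    if lq and rq:
        tiers.add("fdr05_both")
    return frozenset(tiers)


def assign_tiers(
    spikes: Sequence[SpikeTest], p01: float = 0.01, fdr_alpha: float = 0.05
) -> list[MotifRecord]:
    """Label every spike with the significance tiers it satisfies."""
    return [
        MotifRecord(
            motif=s.motif,
            gene_id=s.gene_id,
            exon_id=s.exon_id,
            offset=s.x,
            cluster=s.cluster,
            p_left=s.p_left,
            p_right=s.p_right,
            q_left=s.q_left,
            q_right=s.q_right,
            tiers=_tiers_for(s.p_left, s.p_right, s.q_left, s.q_right, p01, fdr_alpha),
        )
        for s in spikes
    ]


def tier_counts(records: Iterable[MotifRecord]) -> dict[str, int]:
    records = list(records)
    return {tier: sum(tier in r.tiers for r in records) for tier in TIERS}


def differential_me_motifs(
    me_pairs: Sequence[MePairResult],
    records: Sequence[MotifRecord],
    tier: str = "fdr05_either",
    gene_of_pair: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """ME pairs whose two exons carry different motif sets at a tier.

    Motif identity is the nucleotide string (position ignored).  Returns
    one row per reported pair with the motifs unique to each side; pairs
    whose symmetric difference is empty are omitted.  Only pairs with
    status 'm' are considered.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    by_exon: dict[str, set[str]] = {}
    exon_gene: dict[str, str] = {}
    for r in records:
        if tier in r.tiers:
            by_exon.setdefault(r.exon_id, set()).add(r.motif)
        exon_gene[r.exon_id] = r.gene_id
    rows = []
    for pair in me_pairs:
        if pair.status != "m":
            continue
        set_a = by_exon.get(pair.exon_a, set())
        set_b = by_exon.get(pair.exon_b, set())
        only_a = sorted(set_a - set_b)
        only_b = sorted(set_b - set_a)
        if not only_a and not only_b:
            continue
        gene = ""
        if gene_of_pair is not None:
            gene = gene_of_pair.get((pair.exon_a, pair.exon_b), "")
        if not gene:
            gene = exon_gene.get(pair.exon_a) or exon_gene.get(pair.exon_b) or ""
        rows.append(
            {
                "gene_id": gene,
                "exon_a": pair.exon_a,
                "exon_b": pair.exon_b,
                "motifs_only_a": ",".join(only_a),
                "motifs_only_b": ",".join(only_b),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "exon_a", "exon_b", "motifs_only_a", "motifs_only_b"]
    ).sort_values(["gene_id", "exon_a", "exon_b"]).reset_index(drop=True)


def match_external(
    motifs: Iterable[str], external_lists: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Exact-membership flags of each motif against named external word lists.

    Adds an ``all_lists`` column flagging motifs present in every provided
    list.  Empty lists yield zero matches (with a warning).
    """
    import warnings

    lists = {name: set(words) for name, words in external_lists.items()}
    for name, words in lists.items():
        if not words:
            warnings.warn(f"external list {name!r} is empty; zero matches")
    motifs = sorted(set(motifs))
    rows = []
    for motif in motifs:
        row: dict[str, object] = {"motif": motif}
        flags = []
        for name, words in lists.items():
            hit = motif in words
            row[name] = hit
            flags.append(hit)
        row["all_lists"] = bool(flags) and all(flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=["motif", *lists, "all_lists"])


def load_word_list(text: str) -> set[str]:
    """Plain-text word list: one uppercase word per line, '#' comments."""
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(line.upper())
    return words
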