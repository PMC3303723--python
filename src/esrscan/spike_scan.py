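"""Sliding-window conservation profiles, spike detection and FDR correction.

For an exon alignment and a phylogenetic cluster of S species, the
conservation score of the window of length w starting at column x is

    c[x] = (1/w) * sum_{i=x}^{x+w-1} m_i / S

with m_i the number of cluster rows matching the reference residue in
column i.  A *conservation spike* is a window that

1. reaches the cluster's threshold, c[x] >= q+, and strictly dominates
   both non-overlapping flanking windows, c[x-w] < c[x] > c[x+w]; and
2. differs significantly from both flanks by Welch's t test on the
   arcsine-transformed per-column match proportions (p_left < alpha and
   p_right < alpha).

Windows flush against a sequence edge have only one flank; they are tested
one-sided against an elevated threshold (q+ + 0.1, capped at 1).

Per-column proportions are variance-stabilised with arcsin(sqrt(p)) before
testing; the Welch statistic uses sample (n-1) standard deviations with
n = w, and Welch-Satterthwaite degrees of freedom.  P-values are one-sided
(center exceeding flank) by default.  Benjamini-Hochberg adjustment is
pooled over all tested windows of all exons and clusters, separately for
left-flank and right-flank tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment_io import ExonAlignment
from .phylo_clusters import PhyloCluster

__all__ = [
    "ConservationProfile",
    "SpikeTest",
    "conservation_profile",
    "arcsine",
    "welch_t",
    "detect_spikes",
    "bh_fdr",
    "correct_all",
    "scan_exon",
    "spikes_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ConservationProfile:
    gene_id: str
    exon_id: str
    cluster: str
    w: int
    c: np.ndarray              # window scores, index = window start
    column_p: np.ndarray       # per-column match proportions
    column_arcsine: np.ndarray
    reference_row: str = ""


@dataclass(frozen=True)
class SpikeTest:
    """One candidate spike window with its flank comparisons."""

    gene_id: str
    exon_id: str
    cluster: str
    x: int
    w: int
    motif: str
    c_center: float
    c_left: float | None
    c_right: float | None
    s1_left: float | None
    s2_left: float | None
    s1_right: float | None
    s2_right: float | None
    t_left: float | None
    t_right: float | None
    df_left: float | None
    df_right: float | None
    p_left: float | None
    p_right: float | None
    boundary: str = "none"  # none | left_edge | right_edge
    q_left: float | None = None
    q_right: float | None = None

    def significant(self, alpha: float = 0.05, corrected: bool = False) -> bool:
        pl = self.q_left if corrected else self.p_left
        pr = self.q_right if corrected else self.p_right
        if self.boundary == "none":
            return pl is not None and pr is not None and pl < alpha and pr < alpha
        p = pr if self.boundary == "left_edge" else pl
        return p is not None and p < alpha


def conservation_profile(
    aln: ExonAlignment, cluster: PhyloCluster, w: int = 6
) -> ConservationProfile:
    """Window conservation scores c[x] for one exon and one cluster."""
    if w < 2:
        raise ValueError(f"window length must be >= 2, got {w}")
    ref = aln.reference_row()
    mat = aln.matrix(cluster.species)
    matches = (mat == list(ref)) & (mat != "-") & (mat != "N")
    # the reference row always matches itself, even at N columns
    ref_idx = cluster.species.index(aln.reference_species) \
        if aln.reference_species in cluster.species else None
    if ref_idx is None:
        raise ValueError(
            f"cluster {cluster.name!r} does not contain the reference species "
            f"{aln.reference_species!r}"
        )
    matches[ref_idx, :] = True
    column_p = matches.sum(axis=0) / cluster.size
    if aln.columns < w:
        logger.info(
            "exon %s: %d columns < window %d; empty profile",
            aln.exon_id, aln.columns, w,
        )
        c = np.empty(0)
    else:
        c = np.convolve(column_p, np.ones(w), mode="valid") / w
    return ConservationProfile(
        gene_id=aln.gene_id,
        exon_id=aln.exon_id,
        cluster=cluster.name,
        w=w,
        c=c,
        column_p=column_p,
        column_arcsine=arcsine(column_p),
        reference_row=ref,
    )


def arcsine(p):
    """Variance-stabilising transform arcsin(sqrt(p)), radians in [0, pi/2]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def welch_t(
    v1: Sequence[float], v2: Sequence[float], two_sided: bool = False
) -> tuple[float, float, float]:
    """Welch's t for two equal-length windows of transformed column values.

    Returns (t, df, p) with t = (mean(v1) - mean(v2)) / sqrt(s1^2/w + s2^2/w),
    sample standard deviations, Welch-Satterthwaite df, and a one-sided
    upper-tail p (v1 exceeding v2) unless ``two_sided``.  With both spreads
    zero: equal means give t = 0, p = 0.5; otherwise t = +/-inf with p = 0
    or 1 (halved conventions do not apply two-sided).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.size != v2.size:
        raise ValueError("windows must have equal length")
    w = v1.size
    if w < 2:
        raise ValueError(f"window length must be >= 2, got {w}")
    m1, m2 = v1.mean(), v2.mean()
    var1 = v1.var(ddof=1)
    var2 = v2.var(ddof=1)
    se2 = var1 / w + var2 / w
    if se2 == 0.0:
        if m1 == m2:
            return 0.0, float(2 * w - 2), 0.5
        t = math.inf if m1 > m2 else -math.inf
        if two_sided:
            return t, float(2 * w - 2), 0.0
        return t, float(2 * w - 2), 0.0 if m1 > m2 else 1.0
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / (
        (var1 / w) ** 2 / (w - 1) + (var2 / w) ** 2 / (w - 1)
    )
    if two_sided:
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = float(stats.t.sf(t, df))
    return float(t), float(df), float(p)


def detect_spikes(
    profile: ConservationProfile,
    cluster: PhyloCluster,
    alpha: float = 0.05,
    edge_bonus: float = 0.1,
    two_sided: bool = False,
) -> list[SpikeTest]:
    """Candidate spike windows of one profile, with flank Welch tests.

    Interior windows must reach the cluster threshold and strictly dominate
    both flanking windows at x-w and x+w; edge windows (one flank missing)
    must reach the threshold raised by ``edge_bonus`` (capped at 1) and
    dominate the available flank.  Significance is judged at ``alpha``
    against uncorrected p-values via :meth:`SpikeTest.significant`.
    """
    w = profile.w
    c = profile.c
    arcs = profile.column_arcsine
    n = len(c)
    thr = cluster.threshold
    edge_thr = min(thr + edge_bonus, 1.0)
    spikes: list[SpikeTest] = []
    for x in range(n):
        has_left = x - w >= 0
        has_right = x + w <= n - 1
        if not has_left and not has_right:
            continue
        c_left = c[x - w] if has_left else None
        c_right = c[x + w] if has_right else None
        if has_left and has_right:
            boundary = "none"
            if not (c[x] >= thr and c_left < c[x] and c_right < c[x]):
                continue
        else:
            boundary = "left_edge" if not has_left else "right_edge"
            flank = c_right if boundary == "left_edge" else c_left
            if not (c[x] >= edge_thr and flank < c[x]):
                continue
        center = arcs[x : x + w]
        lt = ld = lp = ls1 = ls2 = None
        rt = rd = rp = rs1 = rs2 = None
        if has_left:
            left = arcs[x - w : x]
            lt, ld, lp = welch_t(center, left, two_sided=two_sided)
            ls1 = float(np.std(center, ddof=1))
            ls2 = float(np.std(left, ddof=1))
        if has_right:
            right = arcs[x + w : x + 2 * w]
            rt, rd, rp = welch_t(center, right, two_sided=two_sided)
            rs1 = float(np.std(center, ddof=1))
            rs2 = float(np.std(right, ddof=1))
        spikes.append(
            SpikeTest(
                gene_id=profile.gene_id,
                exon_id=profile.exon_id,
                cluster=profile.cluster,
                x=x,
                w=w,
                motif=profile.reference_row[x : x + w],
                c_center=float(c[x]),
                c_left=None if c_left is None else float(c_left),
                c_right=None if c_right is None else float(c_right),
                s1_left=ls1,
                s2_left=ls2,
                s1_right=rs1,
                s2_right=rs2,
                t_left=lt,
                t_right=rt,
                df_left=ld,
                df_right=rd,
                p_left=lp,
                p_right=rp,
                boundary=boundary,
            )
        )
    return spikes


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correct_all(spikes: Sequence[SpikeTest]) -> list[SpikeTest]:
    """Fill q_left/q_right by pooled BH over all left and all right tests.

    One pool gathers every left-flank p-value across all exons and clusters,
    a second pool the right-flank p-values; each is adjusted separately.
    """
    left_idx = [i for i, s in enumerate(spikes) if s.p_left is not None]
    right_idx = [i for i, s in enumerate(spikes) if s.p_right is not None]
    q_left = bh_fdr([spikes[i].p_left for i in left_idx])
    q_right = bh_fdr([spikes[i].p_right for i in right_idx])
    ql_map = dict(zip(left_idx, q_left))
    qr_map = dict(zip(right_idx, q_right))
    return [
        replace(s, q_left=ql_map.get(i), q_right=qr_map.get(i))
        for i, s in enumerate(spikes)
    ]


def scan_exon(
    aln: ExonAlignment,
    clusters: Iterable[PhyloCluster],
    w: int = 6,
    alpha: float = 0.05,
    edge_bonus: float = 0.1,
    two_sided: bool = False,
) -> list[SpikeTest]:
    """All candidate spikes of one exon across a set of clusters (uncorrected)."""
    spikes: list[SpikeTest] = []
    for cluster in clusters:
        profile = conservation_profile(aln, cluster, w=w)
        spikes.extend(
            detect_spikes(
                profile, cluster, alpha=alpha, edge_bonus=edge_bonus,
                two_sided=two_sided,
            )
        )
    return spikes


def spikes_table(
    spikes: Sequence[SpikeTest],
    alpha: float = 0.05,
    near_ss_distance: int = 10,
    exon_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Spikes as a tidy table, deterministically ordered.

    ``near_splice_site`` flags windows within ``near_ss_distance`` columns
    of either exon end (requires ``exon_lengths`` keyed by exon id; without
    it only the start side can be judged).
    """
    rows = []
    for s in spikes:
        length = (exon_lengths or {}).get(s.exon_id)
        near_start = s.x < near_ss_distance
        near_end = length is not None and (length - (s.x + s.w)) < near_ss_distance
        rows.append(
            {
                "gene_id": s.gene_id,
                "exon_id": s.exon_id,
                "cluster": s.cluster,
                "offset": s.x,
                "length": s.w,
                "motif": s.motif,
                "conservation": s.c_center,
                "p_left": s.p_left,
                "p_right": s.p_right,
                "q_left": s.q_left,
                "q_right": s.q_right,
                "boundary": s.boundary,
                "significant": s.significant(alpha),
                "near_splice_site": bool(near_start or near_end),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "exon_id", "cluster", "offset", "length", "motif",
            "conservation", "p_left", "p_right", "q_left", "q_right",
            "boundary", "significant", "near_splice_site",
        ],
    )
    return df.sort_values(["gene_id", "exon_id", "offset", "cluster"]).reset_index(
        drop=True
    )
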