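"""MAF alignment input and reference-anchored exon projection.

Whole-genome multiple alignments arrive as MAF blocks keyed by species
assembly name (``dm2.chr2L`` style sources).  For motif scanning each exon
is projected onto the coordinates of the reference species: columns where
the reference has a gap are dropped, so a projected column maps 1:1 to a
reference exon base; minus-strand exons are reverse-complemented into
transcription orientation.  Species absent from a covering block appear as
all-gap rows, keeping the species panel constant across columns.

Per-column conservation is summarised as the match proportion m/S: the
number of rows (within a chosen species subset, reference included) whose
residue equals the reference residue, over the subset size.  Gaps and N
never match, except for the reference matching itself.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .splice_graph import ExonNode

__all__ = [
    "MafFormatError",
    "CoverageError",
    "MafRow",
    "MafBlock",
    "ExonAlignment",
    "read_maf",
    "reverse_complement",
    "project_to_exon",
    "column_match_proportion",
    "write_fasta",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")
_ALPHABET = frozenset("ACGTN-")


class MafFormatError(ValueError):
    """Raised on malformed MAF input."""


class CoverageError(ValueError):
    """Raised when alignment blocks do not cover a requested exon."""

    def __init__(self, message: str, missing: list[tuple[int, int]]):
        super().__init__(message)
        self.missing = missing


@dataclass(frozen=True)
class MafRow:
    src: str          # e.g. "dm2.chr2L"
    start: int        # 0-based on the strand given below
    size: int         # ungapped length
    strand: str
    src_size: int
    text: str         # aligned sequence, uppercase

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else ""


@dataclass
class MafBlock:
    rows: list[MafRow]

    @property
    def ncol(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


def read_maf(text: str) -> list[MafBlock]:
    """Parse MAF text into blocks, validating row size consistency."""
    if not text.strip():
        return []
    blocks: list[MafBlock] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # biopython warns on some dialects
        for msa in AlignIO.parse(io.StringIO(text), "maf"):
            rows = []
            for rec in msa:
                ann = rec.annotations
                seq = str(rec.seq).upper()
                ungapped = len(seq) - seq.count("-")
                if ungapped != ann["size"]:
                    raise MafFormatError(
                        f"s-line for {rec.id}: declared size {ann['size']} but "
                        f"sequence has {ungapped} non-gap characters"
                    )
                rows.append(
                    MafRow(
                        src=rec.id,
                        start=int(ann["start"]),
                        size=int(ann["size"]),
                        strand="+" if ann["strand"] in (1, "+") else "-",
                        src_size=int(ann["srcSize"]),
                        text=seq,
                    )
                )
            blocks.append(MafBlock(rows=rows))
    return blocks


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N,-}; gaps and N map to themselves."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement symbol(s): {', '.join(sorted(bad))}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ExonAlignment:
    """One exon's multiple alignment projected onto reference coordinates.

    Rows read in transcription orientation; the reference row is gap-free
    and ``ref_coords[j]`` is the exon-internal offset of column ``j``
    (0..L-1 after full projection).
    """

    gene_id: str
    exon_id: str
    reference_species: str
    rows: dict[str, str]
    ref_coords: np.ndarray
    coverage: float = 1.0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_species not in self.rows:
            raise ValueError(f"reference species {self.reference_species!r} missing")
        if "-" in self.rows[self.reference_species]:
            raise ValueError("reference row must be gap-free after projection")

    @property
    def columns(self) -> int:
        return len(self.rows[self.reference_species])

    @property
    def species(self) -> list[str]:
        return sorted(self.rows)

    def reference_row(self) -> str:
        return self.rows[self.reference_species]

    def matrix(self, species: Sequence[str]) -> np.ndarray:
        """Residues as a (len(species), columns) array of single characters.

        Species without a row become all-gap rows, so a fixed cluster panel
        always yields a fixed number of rows.
        """
        gap_row = "-" * self.columns
        return np.array(
            [list(self.rows.get(sp, gap_row)) for sp in species], dtype="U1"
        )


def project_to_exon(
    blocks: Iterable[MafBlock],
    exon: ExonNode,
    reference_species: str,
    min_coverage: float = 1.0,
) -> ExonAlignment:
    """Project MAF blocks onto one exon's reference coordinates.

    Columns outside the exon or where the reference row is gapped are
    dropped; minus-strand exons are reverse-complemented so rows read in
    transcription orientation.  Raises :class:`CoverageError` when the
    covered fraction of the exon falls below ``min_coverage``.
    """
    blocks = list(blocks)
    all_species: list[str] = [reference_species]
    for block in blocks:
        for row in block.rows:
            if row.species not in all_species:
                all_species.append(row.species)

    length = exon.length
    # per genomic offset within the exon: one column (dict species -> char)
    col_by_offset: dict[int, dict[str, str]] = {}
    for block in blocks:
        ref = block.row_for(reference_species)
        if ref is None:
            continue
        if ref.strand != "+":
            raise MafFormatError(
                f"reference row {ref.src} is on the '-' strand; reference rows "
                f"must be forward-strand"
            )
        if exon.chrom and ref.chrom and ref.chrom != exon.chrom:
            continue
        pos = ref.start
        for j, ch in enumerate(ref.text):
            if ch == "-":
                continue
            if exon.start <= pos < exon.end:
                offset = pos - exon.start
                if offset not in col_by_offset:  # first covering block wins
                    col_by_offset[offset] = {
                        row.species: row.text[j] for row in block.rows
                    }
            pos += 1

    covered = sorted(col_by_offset)
    coverage = len(covered) / length
    if coverage < min_coverage:
        missing = _missing_ranges(covered, length)
        raise CoverageError(
            f"exon {exon.node_id}: alignment covers {len(covered)}/{length} bases; "
            f"missing ranges {missing}",
            missing=missing,
        )

    rows = {
        sp: "".join(col_by_offset[off].get(sp, "-") for off in covered)
        for sp in all_species
    }
    ref_coords = np.asarray(covered, dtype=int)
    if exon.strand == "-":
        rows = {sp: reverse_complement(seq) for sp, seq in rows.items()}
        ref_coords = (length - 1) - ref_coords[::-1]
    return ExonAlignment(
        gene_id="",
        exon_id=exon.node_id,
        reference_species=reference_species,
        rows=rows,
        ref_coords=ref_coords,
        coverage=coverage,
    )


def _missing_ranges(covered: list[int], length: int) -> list[tuple[int, int]]:
    missing: list[tuple[int, int]] = []
    have = set(covered)
    start = None
    for i in range(length + 1):
        if i < length and i not in have:
            if start is None:
                start = i
        elif start is not None:
            missing.append((start, i))
            start = None
    return missing


def column_match_proportion(
    aln: ExonAlignment, column: int, species_subset: Sequence[str]
) -> float:
    """Match proportion m/S at one column for a species subset.

    m counts subset rows whose residue equals the reference residue
    (the reference always matches itself; gaps and N otherwise never
    match).  Species without a row count as gap rows.
    """
    if not 0 <= column < aln.columns:
        raise IndexError(f"column {column} out of range [0, {aln.columns})")
    if aln.reference_species not in species_subset:
        raise ValueError("species subset must include the reference species")
    ref_char = aln.reference_row()[column]
    m = 0
    for sp in species_subset:
        if sp == aln.reference_species:
            m += 1
            continue
        ch = aln.rows.get(sp, "-" * aln.columns)[column]
        if ch not in ("-", "N") and ch == ref_char:
            m += 1
    return m / len(species_subset)


def write_fasta(aln: ExonAlignment) -> str:
    """Projected alignment as FASTA (reference row first)."""
    order = [aln.reference_species] + [
        sp for sp in aln.species if sp != aln.reference_species
    ]
    return "".join(f">{sp}\n{aln.rows[sp]}\n" for sp in order)
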