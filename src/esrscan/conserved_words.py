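"""Extraction of 100%-conserved words from projected exon alignments.

A conserved segment is a maximal run of alignment columns in which every
species row is gap-free and identical to the reference; runs shorter than
the minimum word length (default 5) are discarded.  All substrings of
lengths 5-9 of each segment are emitted as word occurrences, and word
frequencies are counted once per exon by default (the same word at two
offsets of one exon counts once).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alignment_io import ExonAlignment

__all__ = [
    "ConservedSegment",
    "WordOccurrence",
    "find_conserved_segments",
    "extract_words",
    "word_frequencies",
]


@dataclass(frozen=True)
class ConservedSegment:
    gene_id: str
    exon_id: str
    start: int  # exon-internal offsets, half-open
    end: int
    ref_word: str

    def __post_init__(self) -> None:
        if len(self.ref_word) != self.end - self.start:
            raise ValueError("ref_word length does not match segment interval")


@dataclass(frozen=True)
class WordOccurrence:
    word: str
    gene_id: str
    exon_id: str
    offset: int


def find_conserved_segments(
    aln: ExonAlignment,
    min_len: int = 5,
    species: Sequence[str] | None = None,
) -> list[ConservedSegment]:
    """Maximal gap-free, 100%-identical column runs of length >= min_len.

    Conservation is judged across all species rows of the alignment by
    default (``species`` restricts the panel for exploration).
    """
    panel = list(species) if species is not None else aln.species
    if aln.reference_species not in panel:
        panel.append(aln.reference_species)
    mat = aln.matrix(panel)
    ref = aln.reference_row()
    # column conserved <=> every row equals the reference residue and no gaps
    ok = (mat == list(ref)).all(axis=0) & (mat != "-").all(axis=0) & (mat != "N").all(axis=0)

    segments: list[ConservedSegment] = []
    run_start = None
    for i in range(len(ok) + 1):
        if i < len(ok) and ok[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= min_len:
                segments.append(
                    ConservedSegment(
                        gene_id=aln.gene_id,
                        exon_id=aln.exon_id,
                        start=run_start,
                        end=i,
                        ref_word=ref[run_start:i],
                    )
                )
            run_start = None
    return segments


def extract_words(
    segments: Iterable[ConservedSegment], n_min: int = 5, n_max: int = 9
) -> list[WordOccurrence]:
    """Every length-n substring of every segment, n_min <= n <= n_max."""
    if n_min < 1 or n_min > n_max:
        raise ValueError(f"invalid word length range [{n_min}, {n_max}]")
    occurrences: list[WordOccurrence] = []
    for seg in segments:
        L = len(seg.ref_word)
        for n in range(n_min, n_max + 1):
            for i in range(L - n + 1):
                occurrences.append(
                    WordOccurrence(
                        word=seg.ref_word[i : i + n],
                        gene_id=seg.gene_id,
                        exon_id=seg.exon_id,
                        offset=seg.start + i,
                    )
                )
    return occurrences


def word_frequencies(
    occurrences: Iterable[WordOccurrence], distinct_exons: bool = True
) -> pd.DataFrame:
    """Word counts; by default a word counts at most once per exon."""
    if distinct_exons:
        keys = {(o.word, o.gene_id, o.exon_id) for o in occurrences}
        counts = Counter(word for word, _, _ in keys)
    else:
        counts = Counter(o.word for o in occurrences)
    df = pd.DataFrame(
        [(w, len(w), c) for w, c in counts.items()],
        columns=["word", "length", "count"],
    )
    return df.sort_values(
        ["count", "length", "word"], ascending=[False, True, True]
    ).reset_index(drop=True)
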