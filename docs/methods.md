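# Methods

## Mutually exclusive exon detection

A splicing graph is a DAG per gene: nodes are exons (0-based half-open
genomic intervals, merged when start and end coincide), edges are
EST-observed exon-to-exon junctions respecting transcription order.
Cassette annotation is taken from the input document; it is not re-derived
from transcript evidence.

Every unordered pair of cassette exons is flagged by four rules, applied
in a fixed order; each pair keeps exactly one flag:

1. **o** — the exons overlap genomically (half-open interval
   intersection; exons on different chromosomes or strands never overlap).
2. **c** — one exon is reachable from the other (depth-first search from
   each cassette exon; reachability in either direction). Such exons can
   co-occur on a transcript path.
3. **t** — a candidate pair (a, b) is excluded when a overlaps some exon
   c with (c, b) flagged connected: the EST evidence linking c to b,
   together with a and c sharing sequence, makes (a, b) unreliable.
4. **f** — of two surviving candidate pairs (a, b) and (c, b) sharing one
   exon whose non-shared exons overlap, the pair with the *shorter*
   non-shared exon is dropped; equal lengths break toward the
   lexicographically smaller node id.

Rules 3 and 4 are evaluated against the status snapshot left by the
previous rule, which makes the result independent of iteration order and
of node renaming. Surviving **m** pairs are the ME set.

The rule-4 keep-the-longer convention deserves a note: the alternative
reading (always dropping the second pair encountered) is order-dependent
and contradicts the intended outcome on the canonical worked example of
two alternatives of different lengths, so the length-based rule with a
deterministic tie-break was adopted.

An independent oracle (exhaustive enumeration of all source-to-sink
paths for connectivity, with the overlap and competition rules restated
from scratch) is part of the synthetic-fixtures module; the test suite
checks exact agreement on hundreds of seeded random DAGs of up to 12
nodes. Beyond that size path enumeration is combinatorial, which is why
the oracle is a test device, not an alternative implementation.

## Alignment projection

MAF blocks are read with Biopython and validated (declared size must
equal the ungapped row length). Projection onto an exon keeps only
columns whose reference (D. melanogaster) base falls inside the exon and
is not a gap, so projected columns map 1:1 to exon offsets; minus-strand
exons are reverse-complemented into transcription orientation. Species
missing from a covering block become all-gap rows rather than being
dropped, keeping the species panel — and hence S in the conservation
score — constant. When several blocks cover the same reference base the
first block in input order wins. Full exon coverage is required by
default; anything less raises an error listing the missing ranges
(`min_coverage` relaxes this).

Per-column conservation is the match proportion m/S over a species
subset: rows equal to the *reference* residue, the reference counting
itself, gaps and N never matching. Matching against the reference rather
than a column consensus reflects the reference-anchored design — motifs
are reported as D. melanogaster words (a consensus mode would be a
straightforward extension of the same matrix machinery). How absent
species should enter the score is genuinely open; counting them as
mismatches is conservative and is the declared convention here.

## 100%-conserved words

Maximal runs of columns that are gap-free and identical across all
species (N excluded), of length ≥ 5, are extracted left to right; the
grow-window formulation (start at 5 bp, extend until a non-conserved
column) yields exactly these maximal runs. All substrings of lengths 5–9
are tabulated; frequency counting defaults to once per exon, so a word
repeated within one exon counts once but across k exons counts k.

## Conservation spikes

For window length w (default 6, supported 5–9) and step 1, the window
score is the mean of the per-column match proportions:

    c[x] = (1/w) * sum_{i=x}^{x+w-1} m_i / S .

A window is a spike candidate for a cluster when

* `c[x] >= q+`, the cluster threshold, and
* `c[x-w] < c[x] > c[x+w]` — strict dominance over the two adjacent
  *non-overlapping* flanking windows.

Candidates flush against a sequence edge lack one flank; they are
admitted only above `min(q+ + 0.1, 1)` and carry a single flank test.
Gating precedes testing: only gated candidates are tested and reported,
and all tested candidates feed the FDR pools.

Thresholds: a cluster with tree distance s has proximity `q = e^-s` — the
probability that a neutral site is unchanged across distance s — and
threshold `q+ = q + a` with `a = 1 - q(dro1)`. q and q+ are kept at full
floating precision and rounded to six decimals only for display; the
pre-rounded sum differs in the sixth decimal for the dro2 cluster. The
shipped configuration supplies the six tree distances directly, so the
thresholds do not depend on any branch-length aggregation convention;
`cluster_distance` nevertheless offers mean- and max-MRCA-to-tip
aggregation for user-supplied trees (mean is the default, and Newick
input is read as rooted so written branch lengths are honoured).

Significance: per-column proportions are variance-stabilised with
arcsin(sqrt(p)) (radians, [0, π/2]), and each flank comparison uses
Welch's t,

    t = (mean(center) - mean(flank)) / sqrt(s1^2/w + s2^2/w),

with sample (n−1) standard deviations of the w transformed column values
and Welch–Satterthwaite degrees of freedom. P-values are one-sided
(center exceeding flank) by default — the spike definition is
directional, and left/right tests are reported separately; a two-sided
switch exists. With n = w = 6 these tests are deliberately conservative.
Degenerate zero-variance windows: both spreads zero and equal means give
t = 0, p = 0.5; otherwise t = ±∞ with p = 0 or 1. One zero-variance side
(a perfectly conserved center is the common case) is handled by the
ordinary formula, with df collapsing to w − 1.

Multiple testing: Benjamini–Hochberg step-up adjustment, pooled over
every tested window of every exon and cluster, separately for the left
and the right comparisons. Whether gated-out windows should contribute
p-values is ambiguous in principle; here only gated candidates are
tested, so the pools contain exactly the tested comparisons.

## Reporting

Spikes are binned into tiers — both uncorrected p < 0.01, either p <
0.01, either FDR q < 0.05, both q < 0.05 — with motif identity being the
reference-species window substring. For each ME pair, the symmetric
difference of the two exons' motif sets at a chosen tier flags genes
where one exon carries significant motifs its partner lacks — the
candidate regulators of the ME choice. External ESR word lists (plain
text, one motif per line) are intersected by exact string membership; a
motif present in every provided list is flagged. Motifs within 10
columns of an exon end are marked near-splice-site (and can be excluded
with `--exclude-near-ss`), since splice-site signals themselves are
highly conserved.

## Synthetic data

The simulator generates (i) random order-respecting splicing graphs —
exons laid along a chromosome with a configurable overlap-injection
probability (default 0.15), cassette fraction 0.6, edge probability 0.35
between non-overlapping ordered exons — paired with oracle statuses; and
(ii) reference-anchored alignments in which each non-reference residue
matches the reference with a per-column probability: background 0.5
(roughly the exonic identity of the deepest insect comparisons) with
planted fully conserved runs standing in for regulatory motifs.
Mismatches are uniform over the three other bases; indels are off by
default (gap injection is available for format tests). Everything is
bit-reproducible given spec and seed.

The power study uses 15 species, 60-column exons, one planted hexamer at
offset 27, w = 6 and the "all" cluster threshold (0.761221): planted
motifs are recovered as significant spikes at the planted start in ≥ 90%
of 200 seeded replicates, and on null replicates the per-window rate of
passing every gate plus both p < 0.05 stays ≤ 0.05 (the q+ and dominance
gates push it far below the nominal level). These sizes keep the full
suite in seconds while the rates are stable; they are the package's
standard study conditions, not an upper limit.

What the simulations do *not* emulate: phylogenetic correlation between
species (residues are drawn independently per species, not down a tree),
realistic substitution models, indel processes, alignment error, or the
clustered divergence structure of real insect alignments. Passing tests
therefore demonstrate the correctness of the algorithms and the
calibration of the statistics under idealised noise — not discovery
performance on real genomes. A window that is perfectly conserved only
because its species are phylogenetically close will, on real data, be
handled by the per-cluster thresholds rather than by the simulation.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; the DEDB-style XML
  dialect is declared 1-based inclusive and converted on parse.
* A threshold-1 gate (as on the dro1 cluster) admits only perfectly
  conserved windows, so a planted conserved run is recovered as exactly
  one spike; looser thresholds can also admit windows overlapping the
  run by w−1 columns — expected behaviour, since those windows genuinely
  dominate their flanks.
* Alignments shorter than the window yield an empty profile (logged, not
  an error); graphs with fewer than two cassette exons yield an empty ME
  result.
* BH adjustment of an empty p-value list is an empty list; edge spikes
  contribute to one pool only.

## Limitations

* The ME-pair oracle is exponential and restricted to small graphs;
  correctness on large graphs rests on the DFS algorithm itself.
* Exact-string external matching does not consider shifted or partial
  overlaps between motifs of different lengths.
* Conservation spikes are reported per cluster without combining
  evidence across clusters; the same window can appear once per cluster.
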