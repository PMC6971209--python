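# Methods

This note documents the models, rules, and numerical choices behind
`cladesig`, and what the synthetic benchmark does and does not establish
about real data.

## Coordinates and alphabets

All user-facing coordinates are 1-based; ranges are closed intervals. Gaps
(`-`) exist only inside alignments; ambiguity codes (`X` amino acid, `N`
nucleotide) are legal residues that never count as matches and are excluded
from every identity/distance denominator. A reported indel position such as
`130-169` is the span of the displayed query window on the ungapped top
(reference) sequence, not the indel itself; the indel's alignment columns
are reported separately.

## Core-genome stage

**Pairwise identity.** In unaligned mode the two sequences are globally
aligned with match +1, mismatch 0, linear gap −1 (Needleman–Wunsch via
biopython's `PairwiseAligner`); identity = identical pairs / aligned
columns where neither symbol is a gap or ambiguity code. This simple,
fully-specified scheme replaces the internal heuristics of dedicated
clustering tools; it is deterministic and exposed in one place.

**Greedy clustering.** Records are sorted by decreasing length (ties by
lexicographic id). Each record joins the first existing cluster whose
representative (the cluster's seed, hence its longest member) it matches
with identity strictly > `id_threshold` (default 0.5) and length ratio
(short/long) strictly > `len_threshold` (default 0.5); otherwise it seeds a
new cluster. The procedure is a partition by construction and is checked
against a brute-force restatement of the same rule on random instances. It
does not attempt to reproduce the word-filter heuristics or the exact
cluster composition of production clustering tools.

**Paralog resolution.** Concatenation needs one sequence per genome per
family. Where a genome contributes several members, the one most similar to
the representative is kept (ties by id; the representative itself always
survives) and the event is logged. This rule is this package's choice — the
underlying workflow leaves multi-copy handling unspecified.

**Core selection.** A family is core when its distinct-genome count is
≥ `ceil(min_presence × n_genomes)` with `min_presence = 0.8`. Selection is
monotone: raising the threshold never adds families.

**Multiple alignment.** A star-progressive aligner (pairwise global
alignments to the longest sequence, merged under "once a gap, always a
gap") is built in for desk-scale, conserved families. It is not competitive
with profile aligners on divergent data; externally produced aligned FASTA
can be substituted anywhere an alignment is consumed.

**Trimming.** Columns are dropped when their gap fraction exceeds
`max_gap_fraction` (default 0.5) or their majority-residue frequency falls
below `min_conservation` (default 0, i.e. disabled). The kept-column map is
returned for coordinate back-translation. The defaults stand in for an
unreported trimming configuration and are exposed as parameters.

**Concatenation.** Family alignments are concatenated over a fixed genome
list; genomes missing a family carry an all-gap block, and the partition
table tiles the supermatrix exactly. De-gapping a row and splitting it by
partitions reproduces the genome's member sequences.

## AAI

AAI between two genomes is computed on the concatenated core alignment (not
per-gene averaged): 100 × identical / compared over columns where both rows
carry an unambiguous residue. Compared-column counts are kept alongside the
percentages so alternative weightings can be audited. Per-clade summaries
use within-clade pairs only, with the sample (n−1) standard deviation:
a clade with one pair reports an undefined SD and a single-genome clade an
undefined mean (serialized as `NA`), matching the convention of published
AAI matrices where such values "could not be determined".

## CSI scan

**Candidate detection.** Within a family alignment whose rows are
partitioned by a clade map into ingroup and outgroup, maximal gap-column
runs are merged (overlapping runs across rows form one candidate region)
and classified by their presence/absence pattern. Polarity takes the
outgroup consensus as the reference state: a gap confined to the ingroup is
a *deletion in the ingroup*; a gap confined to the outgroup is an
*insertion in the ingroup*. "Most or all" ingroup sharing is quantified as
`min_ingroup_coverage` (default 0.8 of ingroup rows present); ingroup
genomes without a homolog are counted and reported, and a scan-level
`max_ingroup_absent` can make them fatal. The fixed-length rule requires
every sharing row to carry the identical gap run; length variation is
rejected unless `allow_length_range` is set, in which case a length range
(e.g. 2–4) is reported.

**Outgroup exceptions.** A pattern shared by the ingroup plus `k` outgroup
homologs is emitted with status `exceptions(k)` for `k` up to
`report_outgroup_exceptions` (default 2) so that borderline signatures stay
auditable, but it is only ever *exclusive* when
`k ≤ max_outgroup_exceptions` (default 0). Tightening either knob can only
shrink the exclusive set.

**Flank conservation.** Each side of the gap run must contain at least
`min_flank_conserved` (default 5, working range 4–5) conserved columns
among the nearest `flank_window` (default 50, working range 40–50) columns
at which the top row carries a residue. Conservation is assessed across all
compared rows — ingroup and outgroup alike, the stricter of the two
readings of "conserved residues" — under either strict identity (default)
or a majority rule with configurable modal frequency. A candidate whose
side has fewer available columns than the requirement fails as
`edge_truncated`.

**Query window.** The window expands symmetrically from the gap run until
it holds at least 40 ungapped top-row residues (at least 5 beyond the indel
on each side), capped at 100; a shorter protein yields the whole sequence
flagged `short_protein`. These bounds mirror the window sizes used when a
signature region is submitted to a second database search.

**Specificity.** Live database search is out of scope; the scan instead
accepts an ordered homolog pool per family (imported search output or the
simulator's pool) and examines the first `top_n_pool` entries (default
1000, working range 500–1000). Each hit is aligned locally (match +1,
mismatch 0, gap −1) against two reference windows — the ingroup state and
the outgroup state — and is called as sharing the indel iff it scores
strictly higher against the ingroup-state window; ties count as lacking it,
the conservative direction. Status becomes `exclusive` when at most
`max_outgroup_exceptions` non-ingroup hits share the indel and the ingroup
sharing fraction reaches `min_ingroup_coverage`; an empty pool or one
without ingroup hits is `undetermined`. Pool genomes unknown to the clade
map count as non-ingroup, the safe treatment for unrelated hits.

## Signature rendering

Excerpts follow the dash-identity convention: top row unmasked, other rows
print `-` where identical to the top residue, the literal residue where
different, and a blank at gaps; the indel region is boxed with `|` and
ingroup rows precede outgroup rows. Masking is invertible given the top
row, and re-deriving the gap pattern from a rendered block reproduces what
the scanner reported — the excerpt is a lossless view, not an illustration.

## Trees and nucleotide utilities

Tree building is out of scope; trees arrive as newick (parsed with
dendropy, unrooted by default). On an unrooted tree a taxon set is
monophyletic iff it equals one side of some edge's bipartition; on a rooted
tree it must be a node's subtree. Failures report the intruding/excluded
leaves of the best-matching edge. The checker is validated against an
independent edge-removal oracle on random trees.

K2P distance: `d = −½·ln((1−2P−Q)·√(1−2Q))` with transition (P) and
transversion (Q) proportions counted over pairwise-complete columns (gaps
and `N` excluded — the pairwise-deletion convention). Inputs at or beyond
saturation (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) raise an error rather than return
a number. `d ≥ P + Q` on every non-saturated input, with equality only at
zero distance.

## Synthetic benchmark

The generator realizes the shared-ancestor inheritance model directly:
per family a root sequence is drawn uniformly over the 20 amino acids,
evolved down a two-tier hierarchy (root → clade ancestor → genome) by
independent per-site substitution with per-tier probabilities, and each
planted event is applied once to the target clade's ancestral copy — a
deletion removes a contiguous block, an insertion adds one. Flanking blocks
(default 50 residues per side) are substitution-immune by construction, so
flank conservation is guaranteed at any noise level and the noise
parameter stresses only the detection and specificity logic. Families are
omitted per genome with `family_absence_prob`. A two-tier hierarchy rather
than a full birth–death tree keeps truth coordinates exactly derivable;
one seeded generator makes output byte-reproducible.

The reference conditions — 3 clades × 4 genomes + 4 outgroup genomes, 50
families of 200–400 aa, 10 planted events of lengths 1–11 (insertions and
deletions alternating across clades), zero noise, zero absence — are the
generator defaults and the sizes used by the test battery and the
acceptance script; they run in seconds on one CPU. The noisy condition
applies 0.05 per-site substitution on both tiers.

What passing these benchmarks shows: the scanner's bookkeeping
(coordinates, lengths, polarity, sharing patterns, exclusivity logic) is
exact, and its precision is robust to substitution noise outside flanks.
What it does not show: behaviour on real alignments, where flanks do decay,
alignment error creates spurious gap runs, and homolog pools carry
uneven taxonomic sampling. The simulator deliberately omits realistic
substitution matrices (WAG/LG), indel-rate evolution, and codon structure.

## Known limitations

* The star aligner is adequate only for conserved families; divergent
  families should be aligned externally.
* Specificity is relative to the supplied pool; a pool that undersamples
  the outgroup overstates exclusivity, exactly as a shallow database search
  would.
* Dual-reference indel calling can be ambiguous for 1-residue indels in
  low-complexity windows; ties resolve against exclusivity by design.
* Published headline counts for real genome sets (numbers of CSIs per
  clade, AAI matrices over hundreds of genomes) depend on those genome
  sets and live database searches and are not reproduced here; the package
  reproduces the *procedure* and validates it on planted truth.
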