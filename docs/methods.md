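# Methods

`teleomob` re-creates, as a tested pipeline, the comparative mobilome
workflow used in teleost genome studies: build a non-redundant TE
library from genomic copies, annotate genomes against it, read TE
activity history from divergence landscapes, count autonomous-element
families, and relate TE load to genome size across species. This note
records the models, parameter choices and numerical conventions, and
what the synthetic-data tests do and do not demonstrate.

## Synthetic mobilome model

`teleomob.simulate` generates the study conditions every downstream
stage is tested against. A genome of length `L` is drawn i.i.d. at a
configured GC content (default 0.40, a typical teleost-like value).
Each insertion programme plants `copy_number` copies of one consensus:
a copy is optionally 5'-truncated (LINE-like fragmentation, the single
fragmentation mode modelled), mutated by substituting
`round(p * length)` sites chosen uniformly without replacement (each
substituted uniformly among the 3 alternative bases), possibly
reverse-complemented (default strand probability 0.5), and written over
a uniformly chosen non-overlapping window of the background. Placement
is retried up to `max_placement_tries` (2000) and then fails loudly
rather than looping forever.

The per-copy target proportion `p` comes from a configured distribution:
a point mass (one amplification burst), a uniform range (sustained
activity), or a mixture of ranges (multiple bursts) — the shapes that
produce the characteristic landscape profiles (a sharp peak for recent
bursts, a broad mass for extended activity).

The mutation model is substitution-only by default, deliberately
matching the substitution-only assumption of the one-parameter
Jukes-Cantor correction; it keeps each copy's realized divergence
exactly computable by direct string comparison
(`realized_divergence`), which is what makes the truth annotation an
exact oracle. Truncation defaults to off; analyses that want
fragmented copies opt in per insertion programme. Not modelled:
indels, CpG-context mutation bias, nested insertions (available behind
`allow_nesting` but excluded from the tested conditions), transduction
and segmental duplication. Consequently, passing recovery tests show
correctness of the pipeline's logic under its own model assumptions —
they do not certify sensitivity on real genomes, where indels, old
highly diverged relics and low-complexity sequence make masking much
harder.

A single `numpy` generator seeded once drives every draw in documented
order (background, then per copy: truncation, divergence, substitution
sites, strand, placement), so a seed fixes the genome and truth
byte-for-byte.

## Homology masker

The masker finds exact `seed_length`-mer matches (default 11) between
genome and library entry on both strands with a sorted k-mer index,
groups them by (entry, strand, diagonal) — clustering diagonals closer
than 15 so small indels stay in one candidate — and prefilters each
candidate with an ungapped best-segment score along its diagonal.
Surviving candidate windows (the projected library span padded by
`x_drop` bp) are refined with a full local dynamic-programming
alignment (Biopython's C `PairwiseAligner`) under the scoring scheme
+1 match / −1 mismatch / −2 gap open / −1 gap extend. Hits below
`min_score` (default 30 — the score of a 50 bp fragment at 20 %
divergence, consistent with `min_hit_length` 50) are dropped.

Overlaps are resolved greedily by descending score with a deterministic
tie-break (earlier start, then library name); a lower-scoring
overlapping hit is trimmed to its longest uncovered piece, its counts
recomputed over the surviving ungapped blocks, or discarded.

Per-hit divergence is `D = 100 * mismatches / (matches + mismatches)`:
gap columns are excluded, because the Jukes-Cantor correction models
substitutions only. RepeatMasker's `%div` may be CpG-adjusted in some
modes; this masker always reports the raw definition, and the two are
interchangeable at the file level because hits round-trip through the
RepeatMasker `.out` dialect.

On the tested conditions (1 Mb genome, 400 bp consensus, 200 copies,
divergence up to 25 %) the masker recovers ≥95 % of planted bp at
realized divergence ≤20 %, reports ≤1 % of masked bp outside truth, and
tracks true divergence within 1 percentage point on average. Defaults
were chosen from the model (seed specificity, score of the smallest
reportable fragment), not tuned per dataset.

## Library curation

`collect_copies` mirrors the classical consensus recipe: rank hits of a
query element (nucleotide queries via the masker; protein queries via
BLOSUM62 seed-and-extend against all six translation frames), keep the
top non-overlapping hits (cap 40), and extract each with 500 bp of
flanking sequence, clipped at contig ends. Hit significance uses a
shuffled-query null — the best score over a few shuffles of the query,
plus a margin — as a tool-independent stand-in for a BLAST-style
E-value cutoff, which is engine-specific.

Copies are aligned with the pre-installed `mafft` (FFT-NS-2 progressive
mode; near-identical copies need no iterative refinement) and collapsed
by `build_consensus`: per column, the most frequent non-gap base when
non-gap characters form the column majority, ties broken A>C>G>T, other
columns dropped. Because copies are extracted with equal-length flanks,
flanking genomic context can align column-wise rather than as gaps;
`trim_edges` therefore discards edge columns until a run of 10 columns
reaches 60 % majority-base agreement — unrelated flank columns agree at
~25-40 %, genuine element columns at roughly one minus the copy
divergence, so the element boundary is sharp. On simulated copies this
recovers the planted consensus at its exact length and ≥99 % identity.

The 80-80 redundancy rule declares two nucleotide sequences the same
family when a local alignment covers more than 80 % of the *shorter*
sequence at more than 80 % identity over aligned columns. "Of their
length" is ambiguous in common usage; the shorter-sequence convention
(the usual 80-80-80 reading) is the default and the denominator is a
config switch. Families are the single-linkage components of this
pairwise relation — the minimal closure of a pairwise membership rule —
and the cluster representative is a known-library member when one
exists (so classification survives merging), else the longest member
with name as tie-break. `merge_libraries` clusters the union of known
and de novo entries and keeps one representative per cluster; the
output provably contains no 80-80 pair.

## Autonomous elements and families

ORFs are enumerated ATG-to-stop in all six frames; per frame and stop
codon the outermost ORF (first ATG after the previous stop) is
reported, nested internal-ATG ORFs are not listed separately.
Coordinates are 1-based inclusive on the parent and include the stop
codon, so `length_aa = (end - start + 1 - 3) / 3`.

"Intact RT domain" has no universal definition; it is operationalized
as a local BLOSUM62 alignment against a user-supplied reference RT set
covering ≥80 % of the reference at ≥25 % identity (both configurable).
An autonomous LINE needs at least two ORFs and an RT-bearing ORF longer
than 700 aa (strict inequality); an autonomous LTR element needs an
RT-bearing ORF longer than 500 aa. "ORF2" is defined functionally as
the RT-bearing ORF rather than the positionally second ORF, which is
robust to 5' truncation of ORF1. The filter is monotone: lengthening
the RT-bearing ORF or extending RT coverage never revokes autonomy.

Families cluster autonomous elements of the same kind by single linkage
over pairs whose comparison proteins (ORF2 for LINEs, the RT-bearing
ORF for LTRs) reach 80 % amino-acid identity. Identity comes from a
semi-global alignment (terminal gaps free, so truncated elements align
over their full extent); the denominator excludes terminal gap columns
but is floored at the shorter protein's length — without the floor, two
unrelated proteins can overlap on a short coincidental stretch and
report a spuriously high identity, while a genuinely truncated element
aligns over its whole length and is unaffected. "Similarity (80 %)" is
implemented as identity, not a similarity-matrix score. No structural
ORF-architecture criterion beyond the identity rule is applied; clade
labels are user-supplied (via reference-anchored trees), not inferred.

## Divergence landscapes and coverage tables

Raw divergence is corrected with the one-parameter Jukes-Cantor
formula, in percent units on both sides:

    K = -300/4 * ln(1 - D * 4/300)  =  -75 * ln(1 - D/75),   0 <= D < 75

`K` is strictly increasing and convex with `K >= D`; `D >= 75` is
outside the model's domain and is an error at the formula level, while
the landscape builder diverts such hits to a per-group spill bucket (so
mass is conserved and the event is visible rather than silent).

Each hit — fragment-level, not family-averaged — contributes its bp to
the half-open bin `[k, k + width)` (default width 1 percentage point)
of its classification group; bin mass over genome length gives the
genome-fraction landscape. Whether published landscape axes show raw
`D` or corrected `K` is often unstated; a switch selects either and the
default is corrected. Coverage tables count hits (fragments, as in
RepeatMasker summaries, not estimated element copies), union-collapse
bp within each group, and compute percent against the full assembly
length including Ns (switchable); parent rows equal the sum of their
children exactly because upstream overlap resolution makes hits
disjoint. The genome-size~TE-content relation is an ordinary least
squares fit of TE percent on assembly Mb with its Pearson correlation;
fewer than 3 points or zero variance is an error, surfaced as a
documented warning by the cross-species report.

## Phylogenetics

Distances are uncorrected amino-acid p-distances with pairwise gap
deletion by default (complete deletion available); a pair with no
comparable columns is an error naming the pair. Trees are built with
the canonical neighbor-joining algorithm (Saitou-Nei Q criterion),
which is exact on additive distances — the property tests exploit this
by generating random additive trees (4-8 taxa) and requiring exact
topology and branch-length recovery. Q-criterion ties break on the
lexicographically smallest joined taxon pair, so topology is invariant
to input order. Negative branch lengths are clamped to zero with the
deficit moved to the sister branch, preserving the joined pair's path
length. Bootstrap support resamples alignment columns with replacement
under a seeded generator, rebuilds the tree per replicate, and scores
each internal split of the full-data tree by the percentage of
replicates containing it (splits canonicalized relative to the
lexicographically smallest taxon). Trees serialize as Newick with
support as internal node labels. The substitution model and gap
treatment of published MEGA runs are typically unstated; these defaults
are assumptions and are configurable. Maximum likelihood and Bayesian
inference, and alignment construction, are out of scope (alignments are
inputs).

## Pipeline and determinism

`run_pipeline` executes simulate → mask → summarize per species from
one YAML config with one global seed (per-species simulation seeds are
`seed + species_index`), then the cross-species comparison. All config
validation errors are reported together before any stage runs; a stage
failure aborts with the stage named, preserving earlier outputs. The
manifest records input/output SHA-256 checksums per stage; a stage is
skipped when its recorded inputs match and its outputs are present and
unchanged, so deleting a downstream file regenerates exactly it. A
fixed config and seed reproduce every TSV/FASTA/.out byte-for-byte
(manifest wall-clock times excepted).

## Problem sizes used in tests

The test and acceptance workloads use 1 Mb genomes with 200 planted
copies of a 400 bp consensus for masking and landscape checks, 100 kb
sequences for Jukes-Cantor round trips, libraries of up to ~30 entries
for clustering-oracle equivalence, 4-8 taxa for additive-tree recovery
(50 draws) and 100 bootstrap replicates over a 200-column alignment of
12 taxa — sizes at which the brute-force oracles are exact and the full
suite runs in a few minutes on one core. The analysis scripts use four
synthetic species of 0.3-1.2 Mb whose TE loads grow with genome size,
a desk-scale rendition of the four-teleost design.
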