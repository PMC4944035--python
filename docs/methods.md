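# Methods

## Problem setting

The package analyses protein families of two-domain bacterial
transcriptional regulators (a wHTH DNA-binding domain plus an
aminotransferase-like effector domain) in which a candidate subfamily has
been labelled, and the intergenic regions those regulators are predicted to
bind.  Three connected analyses are provided: subfamily clustering with
bootstrap support, detection of specificity-determining positions (SDPs),
and discovery/validation of repeat-structured DNA binding motifs.  All
coordinates are 0-based half-open internally; 1-based numbering appears
only in rendered reports.

## Redundancy filtering

Greedy first-fit clustering at an identity threshold (default 0.90, the
conventional cut for removing near-duplicate regulator sequences before
column statistics).  Identity is matches over columns where both sequences
carry a residue; unequal-length pairs are first aligned globally (BLOSUM62,
gap open −10, extend −1), equal-length pairs are compared positionally.
Records are processed longest-first (input order on ties); each record
joins the first representative at or above the threshold, else founds a
cluster.  This mirrors CD-HIT semantics — greedy and order-dependent, not
an optimal partition — and is deterministic for a fixed input.  The k-mer
pre-filter heuristics of CD-HIT are deliberately not reproduced.

## Distances, UPGMA, bootstrap, clade test

Pairwise distances are counts of differing residues under pairwise gap
deletion (per pair, only columns where both rows have residues are
compared); complete deletion is available as a switch.  Pairwise deletion
is the default because effector-domain alignments are indel-rich and
complete deletion would discard most columns.

UPGMA merges the closest pair of clusters at height d/2 with size-weighted
average linkage.  Ties are broken on the lexicographically smallest pair of
cluster labels (a cluster's label is its smallest leaf name), making the
topology platform-independent.  The output is rooted, binary and
ultrametric by construction.

Bootstrap: columns are resampled with replacement per replicate, distances
and the tree recomputed, and each internal node of the original tree is
annotated with the fraction of replicates containing the same leaf set
(supports in [0, 1]; the conventional 0.90 reporting threshold is applied
at report level, never as a filter).  The clade test asks whether some
internal node's leaf set equals the labelled set exactly; if not, the best
Jaccard-overlap node is reported to quantify near-clades.  The trivial
all-leaves root is excluded from the near-clade search (it would otherwise
dominate whenever the label set covers more than half the leaves).

## SDP detection

Two statistics are computed per alignment column.

**Mutational correlation (Xdet-style).**  For column k and every sequence
pair (i, j) with residues in both rows, S_k(i,j) is the McLachlan
similarity of the two residues (identity matrix available as a fallback)
and F(i,j) is 1 for same-subfamily pairs, else 0.  The score is the
tie-corrected Spearman correlation of S_k with F; columns with constant
similarity score 0 by definition, columns with fewer than two usable pairs
are reported unscored.  Rank correlation makes the score independent of
the similarity matrix's arbitrary scale.

**Correspondence analysis (S3det-style).**  The alignment is encoded as a
binary sequence × (column, residue) indicator matrix, gaps excluded.
Residues observed fewer than max(2, 0.2 × n_sequences) times in a column
are dropped: a category seen once or twice cannot define a subfamily, and
under the chi-square weighting of correspondence analysis rare categories
would otherwise dominate the leading axes with row-specific noise.  The
doubly standardised matrix is decomposed by SVD; sequences are projected
onto the top axes (default 4).  With labels given, clusters are the labels;
without, k-means (fixed seed) with k chosen by silhouette over 2–5.  Each
column's association is the largest absolute difference between cluster
means of its residue-indicator projections, over axes and cluster pairs —
zero when the column carries no group signal, unbounded above.  An earlier
formulation used the correlation ratio (eta-squared), but a statistic
bounded at 1 saturates: when m of N columns share the maximum, no column
can exceed a z-score of √((N−m)/m), and the z-threshold below becomes
unreachable on families with many diagnostic columns.

**Flagging and consensus.**  Per alignment and method, a column is flagged
when its score is ≥ 2.0 standard deviations above the column mean (the
threshold is configurable; published SDP tools report flags without
documenting cutoffs, so the cutoff here is explicit).  Predictions from two
alternative alignments of the same sequences are mapped column-to-column
through the ungapped residue index of a shared reference row and combined:
a column is a consensus SDP iff both methods flag it in one alignment and
at least one method flags its image in the other.  The consensus set grows
monotonically as the threshold is lowered.  Columns are reported both in
alignment coordinates and as 1-based residue numbers of the reference.

**Logo data.**  Per column: residue frequencies over non-gap symbols,
information content log2(|alphabet|) − H in bits (optional small-sample
correction (|alphabet|−1)/(2·ln2·n)), letter heights frequency × IC.

## Motif discovery and scanning

**Discovery.**  Every word of width 5–8 in the input regions is a
candidate, with a word and its reverse complement collapsed into one model
(a dimer's site and its inverted form are the same object).  A candidate
survives when, in at least `min_fraction` (default 0.6) of sequences, it
occurs ≥ 2 times (word or reverse complement, forward strand) with spacer
≤ `max_spacer` (default 40 bp).  Words with fewer than two distinct bases
are rejected as low-complexity.  Survivors are ranked by (sequence
coverage, total occurrences, PWM information content) and refined by one
round of PWM re-estimation from the best per-sequence matches, which
captures single-mismatch variants.  Occurrence pairs are classified direct
(same orientation) or inverted (opposite), with the spacer measured from
the end of the first occurrence to the start of the second: the planted
`GGCCA…TGGCC` pair with 12 intervening bases has spacer 12.  Modal spacer
and spacer dispersion are reported per class.

**PWMs and exact p-values.**  Column frequencies are
(counts + pseudocount·background)/(n + pseudocount); log-odds are base-2
against the background.  The p-value of a match is the exact tail
probability of its score for a random background word, computed by dynamic
programming over the discretised score distribution.  Each log-odds cell is
rounded to a grid of 1/10000 of the score range; word scores are evaluated
on the same integer grid, so the DP equals exhaustive enumeration on the
discretised scores exactly, and differs from the continuous-score tail only
by the probability mass within width × step of the threshold (the
documented discretisation bound, verified against full enumeration for
width 5).

**Uniqueness test.**  Per region, the best match of the score matrix on
either strand is Bonferroni-corrected for the number of scanned offsets ×
strands and called significant below α (default 0.05).  The matrix scanned
is the full-site PWM spanning word + spacer + inverted word, estimated from
the modal-spacer pairs — a short core word alone can never reach
per-region significance (a perfect 5-mer is expected by chance several
times per kilobase), whereas the ~10 informative columns of the full site
give a fine-grained null score distribution under which the Bonferroni
test calibrates close to α and planted regulons are detected with high
power.

## Synthetic data

The generators define the study conditions; their defaults are fixed.

`simulate_family` (defaults: 2 × 20 sequences, 120 columns, 8 planted SDP
columns, 20 conserved columns, leak 0.05, indel rate 0.02): conserved
columns share one residue; each planted column carries residue X in one
group and Y ≠ X in the other, with each row violating independently with
probability `leak`; remaining columns are iid uniform over the 20 amino
acids (the simplest null, keeping information-content expectations
analytic).  With probability `indel_rate` a row loses a run of 1–3
residues; the true alignment keeps the gap at the true position, and the
alternative alignment shifts each gap run by 1–2 columns — re-gapping, not
re-aligning, so the true column correspondence stays recoverable through
the (indel-free) reference row.  Uniform background means the only
group-separating columns are the planted ones: recovery precision and
recall are exact.

`simulate_clustered_family` additionally evolves background columns down a
two-clade tree (root → group ancestor at `between_rate` per site → leaf at
`within_rate`), recording which background columns ended up ancestrally
different (`divergent_columns`) — those separate the groups exactly as
planted SDPs do, which is why recovery against this generator is judged
against the union.  Defaults (within 0.15, between 0.08, 200 columns in the
bundled fixture) give ~78% within-group identity (the family passes a 90%
redundancy filter intact), a clear two-clade distance structure, and few
enough divergent columns that the z-threshold remains attainable.  For a
between/within divergence ratio of ~3 the tests use within 0.05 / between
0.09.  In a two-group family, "separates the groups" and "is an SDP" are
the same property, so a single dataset cannot simultaneously have high
bootstrap support and *only* the planted columns as SDPs; the acceptance
checks therefore measure exact precision/recall on the uniform-background
generator and truth-superset precision on the clustered one.

`simulate_intergenic` (defaults: 20 × 100 bp, word GGCCA, spacer 12):
each region carries word + spacer + reverse complement at a random offset,
optionally a third direct-repeat copy, on an order-0 uniform background
(order-1 Markov background with mild self-preference available).  An
optional per-sequence mismatch at a fixed word position models imperfect
repeats while keeping each pair internally palindromic.

What the generators do **not** model: realistic amino-acid replacement
matrices and rate heterogeneity, alignment-method artefacts beyond local
gap shifts, GC skew and repeat structure of real intergenic DNA, and
promoter elements.  Green tests therefore demonstrate correctness of the
machinery under its stated model, not performance on real genomes.

## Numerical choices and degenerate inputs

UPGMA ties: lexicographic on cluster labels.  Spearman ties: standard
tie correction; constant vectors score 0.  CA of a constant alignment:
all singular values 0 → one cluster, all associations 0.  All-gap
alignment columns: warned about, retained, IC 0.  p-value grid: 1/10000 of
the score range.  k-means: fixed seed from config, n_init 10.  One global
pipeline seed is fanned out to stage seeds through `numpy` SeedSequence;
identical config + seed gives byte-identical outputs.

Problem sizes in the tests and the acceptance script (200 six-leaf oracle
matrices, 20 bootstrap runs at 200 replicates, 20 SDP seeds, 50 motif
seeds, 1000 null regions) are chosen so the whole suite runs in a few
minutes on one CPU while keeping binomial confidence bands tight enough to
be informative.

## Known limitations

* Greedy clustering reproduces CD-HIT's semantics, not its exact cluster
  membership on real data.
* The SDP consensus machinery assumes the two alignments share an
  identical ungapped reference sequence; fundamentally different
  alignments (not mere re-gappings) may leave consensus columns unmapped
  (these are reported, not silently dropped).
* The z-score flagging assumes diagnostic columns are a minority; families
  where most columns separate the subfamilies defeat outlier-based
  flagging (by design — there is no "special" position in that regime).
* Motif discovery seeds on exact word matches; motifs with no conserved
  core word in a majority of sequences are found only through the
  single-round PWM refinement, or not at all.
* The uniqueness test's Bonferroni correction is slightly conservative for
  strongly overlapping windows (wide PWMs in short regions).
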