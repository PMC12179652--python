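# Methods

## Tandem-array detection

**Scoring.** An array is scored by summing integer weights over every
aligned position of the whole array against the tiled consensus:
`score = match·M − mismatch·X − indel·G` where M, X, G count matched,
mismatched and inserted/deleted positions. A perfect array of length L
therefore scores `match·L`; with the default 2-7-7 weights and the
minimum reporting score of 50 this reproduces the 26-bp detection floor
for pure AC dinucleotide runs (24 bp → 48, 26 bp → 52). `percent_matches`
and `percent_indels` use the aligned-column count (M+X+G) as
denominator and round half-up to integers; the denominator is a package
convention, since published profile tables do not define one.

**Search.** Candidate (anchor, period) pairs come from two routes:
exhaustive anchors for periods ≤ 10, and exact 5-mer recurrence-distance
seeding for periods 11–500 (a distance d receives one vote per 5-mer
recurring at spacing d; distances with ≥ 2 clustered votes become
candidates, capped at the 60 best-voted). Sequences of ≤ 60 bp skip
seeding and try every (anchor, period) pair. Each candidate pattern is
refined by optimal Smith–Waterman local alignment of a window around the
supporting cluster against an *unrolled tiling* of the pattern — exactly
equivalent to the classical wraparound dynamic programme over a cyclic
pattern, but optimal without in-row fix-up passes. A column-majority
consensus (ties alphabetical A<C<G<T; majority-deletion columns
dropped) is then re-aligned and kept if it scores higher. The original
tandem-repeat tool's probabilistic Bernoulli-model candidate filter and
significance statistics are deliberately not reproduced; detection here
is fully deterministic. N and IUPAC ambiguity codes score as mismatches
against every base.

**Reporting.** Hits require score ≥ `min_score` (default 50) and a span
of at least 1.8 periods (single pattern copies are not repeats; profile
tables list arrays down to ~1.9 copies). Overlapping candidate arrays
are resolved by score, then smaller period, then leftmost start — so an
AC run is reported at period 2, never at period 4 or 6. Coordinates are
0-based half-open internally; report files print 1-based inclusive.

**Two-pass ITS protocol.** Pass 1 scans the full sequence at 2-7-7;
pass 2 re-scans only the ITS2 window at 2-3-5 and lifts coordinates
back. The published protocol delimits the second pass by alignment
columns; this implementation takes a per-sequence ITS2 interval from the
annotation instead (the alignment-column route is available through
`infer_insertion_boundaries`). Lowering the penalties can only raise an
array's best score, which is why the sensitive pass finds repeats the
primary pass misses.

**Consensus comparison.** Core motifs are compared by exact global
alignment under unit match/mismatch/gap costs, identity = matches ÷
alignment columns × 100, optionally maximised over rotations of the
second motif (cyclic mode). This replaces a BLASTn-based comparison
with a deterministic, dependency-free equivalent.

**Quality screen.** Sequences with more than 5% non-ACGT bases are
refused unless explicitly overridden.

## GCPSR delimitation

Candidates are all well-supported clades (BS ≥ 70 and PP ≥ 0.95; the
weaker of the two bands is binding because the bands are conjunctions)
of every single-locus genealogy, outgroup excluded, whole-ingroup clades
excluded. A candidate is rejected if any genealogy contains a
well-supported clade that overlaps it without nesting; an unsupported
conflicting topology does not contradict (otherwise any poorly resolved
tree would contradict everything). A genealogy sharing fewer than two
taxa with the candidate, or containing no taxon outside it, is
uninformative. When only BS is present (an ML-only node),
well-supportedness is decided on BS alone and flagged; absence of a
support value is not evidence of conflict.

Identical taxon sets are merged across loci. Mutually incompatible
accepted clades are resolved deterministically: more independent
supporting linkage groups, then higher minimum support, then smaller
clade, then lexicographic taxon order. Lineages are reported at the
*maximal* accepted clades; nested accepted clades appear as
substructure, not separate species. A lineage whose entire support
comes from one linkage group (ITS and LSU are inherited together and
count once) is a putative phylogenetic species. A supplied multilocus
tree only flags lineages it contradicts; it never removes them. Whether
putative lineages on non-overlapping locus sets are conspecific is a
human judgement; the report surfaces them for review rather than
automating the merge.

A column is parsimony-informative iff at least two distinct unambiguous
states each occur in at least two sequences; gaps and ambiguity codes
are missing data.

## Morphometrics

Q (length/width) and Vm (πLW²/6, μm³) are computed per spore and then
averaged within each collection; the grand values are unweighted means
across collection means and the sd is across collection means (n−1).
Per-spore averaging is why a printed Vm exceeds πL̄W̄²/6 of the printed
mean dimensions (Jensen's inequality); the package asserts this
direction rather than equality. Display rounding: dimensions 0.1 μm,
Q two decimals, Vm integer. A single collection reports sd 0 with a
flag.

The isoprobability ellipse at level α has semi-axes √(λᵢ·k²) along the
covariance eigenvectors with k² the chi-square(2 df) quantile at α
(k² = −2·ln(1−α)); membership is squared Mahalanobis distance ≤ k²,
boundary inclusive. Ellipses can be built from raw spores or from
collection-mean points (the latter matches how species are compared in
size-distribution figures); both modes are exposed.

## Synthetic data

The genealogy generator emulates a multi-locus study design: loci with
declared linkage groups (ITS-LSU linked; tef1-α and rpb2 independent),
an outgroup appended to every tree, per-locus specimen masking, and a
per-species per-locus concordance probability. Topologies are uniform
random joins (coalescent-style); no molecular evolution, branch lengths
or rate models are simulated, so passing tests demonstrate the logic of
delimitation, not robustness to inference error. True-species clades
draw supports from (BS 95–100, PP 0.99–1.00) and all other clades from
(BS 5–69, PP 0.50–0.94) by default, i.e. below the well-supported
threshold — the study conditions for exact-recovery checks.

The marker generator plants a pure AC microsatellite (default 26 bp,
the detection floor) centred in ITS1 and a minisatellite of ⌊κ⌋ full
copies plus a ⌊(κ−⌊κ⌋)·p⌋-base prefix (default: 80-bp consensus,
κ = 2.8, 5% substitutions, no indels — a realistic fuzzy ITS2 insertion)
centred in ITS2, with two junction-guard bases on each side so arrays
cannot extend into the random backbone by chance. Mutations apply to
the minisatellite only; truth records carry exact planted intervals
(0-based half-open), the consensus, and the pre-mutation tile. Defaults
for the spore generator are a 19-collection survey of 31 spores per
collection around means (11.6, 5.0) μm with covariance diag(0.36, 0.04)
μm² and 0.3 μm between-collection jitter; non-positive draws are
rejected and redrawn (truncation preserves the Gaussian bulk shape).
Real measurement data differ in ways the generator does not emulate:
within- vs between-basidiome variance structure, observer rounding, and
non-Gaussian tails.

Fixed 100-bp flanks (`LEFT_FLANK`, `RIGHT_FLANK`) are provided for
embedding repeat constructs; they were verified once to contain no
scoring array under either weight setting and to be unable to extend an
AC-phase run across the junction, so detection-floor sweeps are exact
and seed-independent.

All generators derive every random choice from a single seeded
generator per call; equal parameters give byte-identical output.

## Numerical and test design choices

* The oracle-equivalence check compares the raw maximal array score
  (substring-seeded, no reporting thresholds) against an independent
  brute-force enumeration over every (start, end, period ≤ 10) with a
  separate global-per-start dynamic programme. It enumerates all {A,C}
  strings to length 11 exhaustively (4094 strings, covering ≥ 2 copies
  at every period ≤ 5 and the full candidate machinery) plus a seeded
  sample of 300 longer strings to length 20.
* Monte-Carlo checks (consensus recovery from mutated arrays, ellipse
  coverage) use 100 replicates and 10⁵ draws respectively, with
  tolerances derived from the binomial standard error, not tuned.
* Degenerate inputs: empty sequences yield empty hit lists; a window
  outside the sequence, ragged alignments, singular covariances,
  non-positive dimensions and empty partitions raise `ValueError`.

## Known limitations

* The detector is not engineered for genome-scale input; it targets
  marker-length sequences (~10² – 10⁴ bp).
* Candidate seeding requires an exact 5-mer recurrence for periods
  > 10; arrays mutated far beyond ~15% per base may be missed — the
  published use case (≥ 96% intra-species similarity) is far inside the
  safe regime.
* Delimitation follows the rule-based genealogical concordance
  criterion only; no Bayesian species-delimitation model is provided.
* The species-level result of the original multi-locus study (19
  phylogenetic + 8 putative species) depends on its supplementary
  single-locus trees, which are external downloads; with those trees
  supplied as a manifest, `boletax delimit` reproduces the analysis
  route, but no such check can run from this repository alone.
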