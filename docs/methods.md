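# Methods

## The classification model

An intron is represented by a two-dimensional score vector: the log₂
U12/U2 probability ratio of its 5′ splice-site window and of its best
branch-point 12-mer. Both components are position-weight-matrix (PWM)
log-odds scores; a flat pseudo-count frequency of 0.001 is added to
every matrix cell at scoring time, so zero-frequency bases incur a
large (≈ −8 bit for a near-unanimous column) but finite penalty, and an
N in the sequence contributes exactly zero bits (the pseudo-counts
cancel). The assumption underlying the two-dimensional representation
is the standard one in this literature: U2- and U12-type introns are
distinguished by their extended donor motif and by the presence
(U12) or absence (U2) of a tight branch-point consensus, and these two
signals suffice for near-perfect linear separation of the classes.

### Coordinate conventions and windows

Genomic coordinates are 1-based inclusive throughout, matching
GFF3/GTF. Splice-site position labels skip zero: +1 is the first intron
base, −1 the last. The 5′SS window spans −3..+9 (three exonic plus nine
intronic nt, 12 columns); the branch-point search region spans −55..−5
relative to the last intron base, so a full region holds 51 nt and 40
candidate 12-mers. Ties in the 12-mer scan are broken toward the
3′-most (branch-point-proximal) position, reflecting the positional
bias of real branch points.

Degenerate inputs: windows overrunning a chromosome end are N-padded;
the BPS region of a short intron is truncated at the intron 5′ end
rather than N-padded (left-padding would admit candidate 12-mers lying
partly in padding, which would score artificially close to zero).
Introns shorter than 30 nt are extracted and reported but flagged
`too_short` and excluded from classification — below that floor the
5′SS and branch-point windows overlap and the two scores stop being
independent measurements. Flagged introns are never silently dropped;
they carry a `too_short` call in the output table.

### The empirical U2 branch-point matrix

U2-type introns have no extended BPS consensus, so no meaningful U2 BPS
matrix can be curated. Instead it is derived from each input intron set
(e.g. each species) separately: all introns with a 5′SS score below the
95th percentile of the set (linear-interpolation quantile, strictly
below) are taken as almost-certainly-U2; each contributes its
best-scoring 12-mer under the U12 BPS matrix alone (at this stage no U2
matrix exists, so "best" means maximal U12 log-probability); the pooled
winners form the U2 BPS matrix. Defining the U2 matrix by the *most
U12-like* branch points found in real U2 introns makes the final BPS
log-odds conservative. Scoring is therefore two-pass: 5′SS scores
first, then the empirical matrix, then BPS log ratios for everything.
At least 20 scored introns are required — below that the percentile
estimate is unstable — and a fully homogeneous score distribution
(empty strictly-below set) is an error rather than a silent fallback.

Note one deliberate property of this construction: because each
contributing intron donates its *maximum-scoring* 12-mer, the matrix
converges (in n) to a selection distribution that is biased toward the
U12 consensus even when the underlying regions are uniform random
noise. That is by design (it is what makes the score conservative); the
test suite checks convergence, not uniformity.

### Subtype dispatch

PWMs are keyed by (class, motif, subtype). Introns with AT-AC termini
are scored with AT-AC U12 matrices where available; GC-AG introns use a
GC-AG U2 donor matrix where available; all other termini — including
non-canonical ones — fall back to GT-AG matrices of both classes.
Subtype matrices are built from training data only when at least five
training sequences carry the corresponding donor, to avoid
near-singular matrices.

When building the U12 BPS matrix from training branch-point regions,
candidate 12-mers must carry an A at position 9 or 10 (the branch
adenosine); violators are excluded from matrix building but not from
scanning. Regions of exactly 12 nt are used directly; longer regions go
through a two-round refinement (pool all branch-A 12-mers → provisional
matrix → each region's best branch-A candidate → final matrix).

### Classifier

A linear-kernel SVM (scikit-learn `SVC`) on per-feature standardized
scores. `IntronClassifier` follows the scikit-learn estimator contract
(`fit`/`predict`/`predict_proba`/`get_params`, fitted attributes with
trailing underscores) and composes with sklearn model selection.

* **Imbalance.** Real training sets have U2 ≫ U12. No class weights are
  applied; imbalance is addressed in model selection by using balanced
  accuracy, (sensitivity + specificity)/2 with U12 positive.
* **Penalty C.** Chosen by iterative cross-validation: round one scans
  a 13-point logarithmic grid over 10⁻³..10³ by stratified 5-fold CV on
  balanced accuracy; each round re-grids between the neighbors of the
  best C (ties going to the *largest* C, the more conservative
  wide-margin choice on plateaued data); after 3 rounds the arithmetic
  mean of the final range endpoints is returned. On well-separated data
  CV accuracy plateaus over orders of magnitude of C, so the precise
  grid geometry matters little; folds, rounds and grid are all
  parameters.
* **Calibration.** Decision values from out-of-fold predictions are fit
  with a slope-only sigmoid p = 1/(1+e^(−a·d)) (logistic regression
  without intercept). The slope-only form guarantees p = 0.5 exactly on
  the decision boundary and strict monotonicity in the decision value —
  both part of the module contract; a two-parameter Platt fit
  guarantees neither. The slope is clamped positive; with the decision
  axis oriented toward U12 a negative fitted slope occurs only on
  unlearnable (chance-level) data, where clamping leaves all calls
  U2-type.
* **Threshold.** p(U12) ≥ 0.90 → U12-type. The high threshold trades
  sensitivity for a near-zero false-positive rate; genuinely ambiguous
  introns (degraded donor *and* branch point) fall below it by design.
* **Determinism.** One seed drives CV shuffling everywhere; the same
  seed yields byte-identical model files (plain-text, versioned:
  standardization, weights, bias, C, calibration slope).

## Annotation handling

GFF3 and GTF dialects are both parsed (via gffutils); transcript
attribution comes from `Parent`/`transcript_id`. The longest isoform
per gene is the one maximizing summed feature length of the run's
feature kind, ties broken by lexicographically smallest transcript id.
Phase of a CDS-defined intron is (summed upstream CDS length) mod 3 in
transcript orientation; exon-defined introns have undefined phase.
Exon- and CDS-defined runs are merged by exact
(chrom, start, stop, strand) key, the CDS record winning — exact
matching is the right granularity because both runs come from the same
annotation, so coordinates of shared introns are identical. Rank (1 =
5′-most) is numbered within the longest isoform.

## Statistics

* **Phase bias**: per-class chi-squared goodness-of-fit of phase counts
  against a uniform null (1/3 each, 2 df). The null fractions are a
  parameter; uniform is the default because no alternative null is
  implied by the data model. The significance threshold is the user's,
  not hard-coded.
* **Clustering of U12 introns in genes**: under independent placement
  the number of U12-bearing genes with ≥2 U12 introns is
  Binomial(n, p), n = genes with ≥1 U12 intron,
  p = 1 − (1 − x)^(m−1), x = genome-wide U12 fraction, m = mean introns
  per intron-bearing gene (interpretation of "average introns per
  gene"; a parameterizable choice). Both the point mass P(X = k) and
  the upper tail P(X ≥ k) are reported; the tail is labeled the
  p-value, since "probability of observing at least the observed
  clustering" is the conventional test.
* **Splice-variant dedup**: coordinate rows become edges between
  genomic position nodes; connected components are unique introns
  regardless of how many alternative donors/acceptors they carry; the
  representative is the lexicographically smallest (start, stop).
* **Wobble-G count**: the 61 sense codons of the standard code group
  into 20 amino-acid families; 13 contain a codon ending in G, so the
  −1 exonic base of a phase 0 intron can synonymously be G in 13 of 20
  families.

## Orthology

Reciprocal-best-hit detection and global protein alignment are consumed
as inputs (aligned-FASTA pairs), not executed. An intron is anchored at
residue ⌊upstream CDS nt/3⌋ + 1 with its phase. Two anchors link iff
they map to the same alignment column, share phase (the strictest
reading of positional conservation, and consistent with phase being
conserved in orthologous introns), and local identity within ±10
columns is ≥ 40% (identical non-gap pairs over columns examined; the
window truncates at alignment ends without padding, keeping the
observed denominator). Groups are all maximal cliques of size ≥ 2 of
the link graph (pivoting Bron–Kerbosch via networkx), so every member
of a group is a recorded ortholog of every other member; a node may
belong to several groups. Clique listing is exponential in the worst
case, so a 200 000-node ceiling guards against accidental dense inputs.

## Synthetic data

The simulator emulates exactly the features the method measures and
nothing else: per-intron donor 12-mers and (for U12) branch-point
12-mers sampled around configurable consensus strings with per-position
fidelity (default 0.95 — a planted base matches consensus with
probability 0.95, else is uniform over the other three bases); log-normal
intron lengths (default μ=4.8, σ=0.35 on the log scale, median ≈ 120 nt,
clamped to ≥ 70 nt so a full branch-point window fits); uniform random
background; alternating gene strands; fully coding genes with total CDS
a multiple of 3. Class counts are planted exactly
(round(u12_fraction × introns)), so a stated composition such as
"1000 U2 + 10 U12" is a generator condition rather than a random draw.
Default consensus strings (U2 donor CAG|GTAAGTTTT, U12 donor
AAG|GTATCCTTT, U12 branch point CTTTCCTTAACT) follow the canonical
motifs of the two classes; they are configuration values, not claims
about any particular curated matrix set.

Not modeled: codon usage, GC content, polypyrimidine tracts, splicing
regulation, alternative isoforms, overlapping genes. Consequently,
passing tests demonstrate correctness of the machinery (extraction
arithmetic, scoring, selection, calibration, grouping) under known
truth — they do not demonstrate classification accuracy on real
genomes, which depends on the quality of real training data.

Demonstration training sets are generated at curated-set scale — 5000
U2 and 500 U12 sequences, preserving the ≈10:1 imbalance of real
curated collections (U12 sets number in the hundreds). Much smaller
U12 training sets (tens of sequences) leave PWM columns with zero
counts, where the pseudo-count turns single mutations into multi-bit
score cliffs; that regime is exercised in tests but not used as the
demonstration condition.

## Problem sizes

Test and acceptance runs use a 1010-intron genome (202 genes × 5
introns), 100 000 Monte-Carlo draws for the binomial check and 1000
replicates for the p-value calibration check — sizes at which every
targeted property is already stable, chosen as the package's standard
demonstration scale.

## Known limitations

* Exact-coordinate matching when merging exon- and CDS-defined runs
  cannot pair introns whose boundaries differ between the two feature
  sets (e.g. annotation inconsistencies).
* The 84–90% probability band sometimes displayed in this literature is
  treated purely as a display convention; only the 0.90 threshold has
  call semantics here.
* Orthologous-intron linking requires exact column *and* phase
  equality; introns shifted by intron sliding are not linked.
* The empirical U2 BPS construction assumes U12-type introns are < 5%
  of the input; on pathological inputs (mostly-U12 sets) the 95th
  percentile filter no longer isolates U2-like introns.
* No nonlinear kernels, 3′SS scoring, or trans-splicing support.
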