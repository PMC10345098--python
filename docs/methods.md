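# Methods

## The MinSeq representation

A (k, g, l) MinSeq is a k-mer of specified bases, a spacer of g unspecified
positions, and an l-mer of specified bases; `AACG-3-GCTTA` matches
AACGNNNGCTTA.  A weighted set of such patterns summarizes a DNA–protein
interactome without forcing a single alignment or fixed motif length, which
matters for factors (e.g. nuclear receptors) that bind half-sites in
direct/inverted/everted orientation across a range of spacers.

Default shape ranges are k, l ∈ 3..8 (plus pure k-mers with l = 0),
g ∈ 0..8, total span capped at the read length (20 nt).  These ranges are
configuration, not biology: they bound the enumeration at roughly 300 shape
classes per run while covering the dimeric arrangements of hexameric
half-sites with spacers up to 8 nt.  Note that a contiguous stretch of
specified bases is representable in several (k, 0, l) classes; such
duplicates carry identical counts and weights and are ranked adjacently by
the deterministic tie-breaks, so they are cosmetic rather than harmful.

## PAGLO: the library background model

Expected pattern frequencies come from a position-associated inhomogeneous
Markov model of the unselected library (or of a bead-only control run):
each read position i has its own conditional distribution
P(base_i | previous r bases), estimated with an additive pseudocount
(default 1).  The default order r = 1 captures the dominant positional and
dinucleotide composition of a SELEX library at 1e5-scale read depth without
over-parameterization (an order-2 model has 16 x 4 parameters per position
and needs correspondingly more reads); order and pseudocount are recorded in
the serialized model.

Pattern probabilities are computed by exact forward marginalization over the
chain: specified positions constrain the emission, gap positions and
positions outside the window are summed over by transfer-matrix products.
This keeps gap probabilities exact at any order — a gap is never treated as
an independent factor.  The implementation is verified against exhaustive
enumeration over all 4^6 reads for orders 0–2 to 1e-12.

## Counting, thresholding, enrichment, weighting

Every window of every bound read increments exactly one pattern per shape
class, so per-class totals equal N_reads x (L - span + 1); reads containing
ambiguous bases still count toward T_b but are excluded from pattern
counting, since patterns are defined over A/C/G/T.  Counting is
strand-specific (patterns are counted as read); all downstream *scoring* is
double-stranded.  A consequence worth knowing: a motif and its reverse
complement are equivalent discoveries, and which orientation ranks first
depends on sampling noise.

Two threshold policies implement the count cutoff C^T ("below C^T is
discarded", i.e. C_b >= C^T keeps):

* absolute (default C_T = 10): simple, predictable, appropriate when the
  goal is a rich ranked table;
* poisson (alpha = 0.01): per shape class the null mean count is
  lambda = windows / 4^(k+l); the effective C^T is the smallest c with
  P(Poisson(lambda) >= c) <= alpha / M, where M is the total number of
  patterns across all enumerated classes.  The Bonferroni correction is
  global rather than per-class so that a signal-free run retains nothing
  with probability about 1 - alpha (verified empirically: plant-free
  simulations at 1e5 reads retain zero patterns).

Enrichment follows E*(x) = (C_b/T_b) / (C*/T).  Records whose expected
count C* falls below a floor (default 0.01 reads) are flagged and excluded
from ranking: below that floor the ratio is numerically meaningless, while
above it a threshold-passing count (>= 10) cannot be Poisson background
(P(X >= 10 | 0.01) ~ 1e-30).  The floor is deliberately far below 1 — long,
highly specific patterns (12+ specified bases) have fractional expected
counts at realistic sequencing depth and are precisely the discoveries of
interest.

Weighted enrichment W(x) = log2 E*(x) / (k + l) expresses enrichment per
specified base, making patterns of different lengths commensurable; the
scheme is swappable.  Ranking sorts by W, then raw E*, then pattern text,
so output order is independent of input order.

### Calibration

On library-vs-library comparisons the enrichment is unbiased (mean E* ~ 1)
in shape classes whose null mean count lambda is well above C^T.  In classes
with lambda near or below C^T the count threshold itself conditions on
upward fluctuations and the retained-pattern mean exceeds 1 — a property of
truncation, not of the estimator.  Calibration checks therefore measure the
mean over classes with lambda >> C^T.

## OMP reduction

The ranked table is compressed by a modified orthogonal matching pursuit.
Atoms are strand-aware containment indicator vectors of candidate MinSeqs
over a probe set (default: the distinct bound reads, with read-count
frequencies as the target signal).  Each iteration selects the atom with the
highest norm-normalized correlation with the residual, refits all selected
atoms by nonnegative least squares, and stops at the atom budget, at a
relative residual below tolerance, or when no atom correlates positively.
The nonnegative refit guarantees a non-increasing residual and nonnegative
weights.  Candidates default to the top 2000 records by W — OMP's job is
redundancy removal among already-enriched patterns, not rescue of
sub-threshold ones.

## Sequence logos

The top-ranked record seeds a PWM: the seed is extended by 6 N positions on
each side, and at each position each base is substituted in turn; the
substitution pattern is counted in the bound reads, normalized by the
library model to an enrichment, and the four per-base enrichments form the
column after normalization to sum 1.  Spacer columns stay uniform.
Substitution windows extending past the read boundary are counted only where
they fit (normalization is by the matching expected count, so partial
occupancy cancels); a fully unfittable column falls back to uniform.
Substitution counting is exact-match; columns are built from enrichments
rather than raw counts so library composition cannot masquerade as
specificity.

Estimates for the remaining records use the PWM odds product
(weight / 0.25 over the record's specified positions, spacer columns
skipped, maximized over strands and alignments) scaled so the PWM's own
seed maps to its seed enrichment.  For residual subtraction the estimate is
converted to weighted units as log2(max(estimate, 1)) / (k + l) — the same
per-base log scale as W — and the iteration re-ranks on
residual = max(0, W - estimate).  Without this conversion an extracted
motif would fail to suppress its own sub-patterns (odds products scale
exponentially with pattern length while W is logarithmic per base), and
every subsequent "motif" would be a fragment of the first.  Iteration stops
at max_iter (default 10) or when the total residual drops below 5% of the
initial total weighted enrichment.  PWMs are written in MEME minimal motif
format.

## Peak Assign

Peaks (BED intervals with sequences from an indexed FASTA; minus-strand
intervals reverse-complemented) are scored with the MinSeq model: windows of
the model's maximum span slide over the sequence, the window score
aggregates contained records (max by default, sum available), and the
sequence score is the window maximum; both strands are searched by default
and non-ACGT characters never match a specified base.  Negatives are
mononucleotide permutations of each peak (2 per peak by default; a
dinucleotide-block shuffle is available behind a flag).  The ROC varies a
strict ">" threshold over scores; AUROC uses the trapezoidal rule with
midrank tie handling.  Each positive peak also gets
S = max over detection thresholds of TPR/(TPR+FPR), which is 1 for a peak
detected at zero false-positive rate and bounded below by 0.5 (the value at
the all-detected threshold).  The binding-mode heatmap partitions the model
into monomer + {DR, IR, ER} x spacers 0–8 (28 categories) against a given
IUPAC half-site; records matching several categories (palindromic
half-sites) are assigned deterministically in the order monomer, DR, IR, ER
with smaller spacers first, and category S scores are computed against the
global permuted-negative pool.

## SNP Align

Each variant's +/-20 bp reference and alternate windows are scored with the
model; the effect size is log2((E_alt + eta)/(E_ref + eta)) with
eta = min(10, 10% of the model's maximum enrichment) guarding against
division by small numbers; |log2FC| >= 1 (2-fold) calls a binding-site gain
or loss.  Input rows with indels, multi-allelic records, or reference
alleles disagreeing with the genome are skipped with counted warnings.

## Landscapes

Ring SELs assign every k-mer to its minimal-Hamming-distance ring around a
(possibly degenerate) seed; ties among placements break to the leftmost
offset.  Ring ordering is deterministic: ring 0 sorts by flanking bases then
seed position; mismatch rings by mismatch positions, substituted bases
(alphabetical), flanks, then position.  Gapped SELs expand a two-monomer
degenerate seed per arrangement and gap 0..8; the substitution order is
lexicographic over degenerate positions and shared across gaps, so a given
substitution keeps its x-coordinate in every row.  DiSEL max-normalizes two
landscapes to 1 and subtracts, giving values in [-1, 1].  Landscapes
serialize to TSV; no plotting is required for any analysis.

## Interactome comparison

For each pair of tables the union of their top-100 patterns (OMP-weighted
when available, otherwise by W) forms the profile; a pattern absent from one
table is valued by scoring its concrete sequence (gaps as N) against that
table's full model — identical code path to peak scoring.  Similarity is
Pearson's r; clustergram order comes from agglomerative clustering
(complete linkage by default, average available) on Euclidean distances
between correlation rows.

## The synthetic SELEX generator

The generator emulates a 20-nt random-region HT-SELEX experiment at desk
scale: a round-0 library (default 1e5 reads, uniform composition, optional
bias), then 3 rounds in which the pool is resampled with replacement, each
read weighted by affinity ** selection_sharpness.  Affinity is
exact-containment: the maximum planted affinity whose pattern occurs in the
read on either strand, baseline 1.  Proportional (soft) resampling models
equilibrium binding; large sharpness approaches hard selection.  Resampling
stands in for the bind–wash–amplify cycle; PCR errors and sequencing errors
are not modeled (an optional GC-bias multiplier exists behind a flag).

One design point deserves emphasis.  A real SELEX library (~1e12 molecules
over 4^20 sequences) contains every 12-base site many times even though a
sequencing-depth-sized *sample* of it almost never does (expected
occurrences of a 12-specified-base pattern in 1e5 20-nt reads: ~0.1).
Because selection here acts on the sampled pool and resampling cannot create
sequences, the generator restores that molecular diversity by seeding each
planted pattern into the library at a small `site_frequency` (default 1e-3:
~100 of 1e5 reads carry one instance at random offset, strand and gap
fill).  Selection then amplifies carriers across rounds exactly as the
bound fraction grows in the experiment (with the defaults: ~0.1% → ~2% →
~28% → ~88% across rounds 0–3).  With no planted patterns, or all
affinities equal, every round is statistically a plain resample of the
library.

What the simulation does *not* reproduce about real data: sequencing error,
PCR substitution error and amplification bias, carrier-molecule ("clonal")
structure beyond what resampling induces, binding cooperativity, and graded
affinity of near-cognate sites (affinity is all-or-none).  Passing
recovery tests therefore demonstrates the statistical machinery — counting,
normalization, ranking, logo extraction — under a controlled ground truth,
not robustness to every artifact of a wet experiment.  One real-data
artifact the simulation *does* produce is clone amplification: a single
round-0 read resampled thousands of times makes its random flanks look
enriched.  Deep selection (strong affinity, several rounds, library not
much larger than depth) therefore produces high-W junk patterns — visible
in the defaults as patterns combining a half-site with arbitrary flanking
bases below the planted pattern's rank.  Larger libraries or fewer rounds
reduce it, exactly as in the experiment.

## Problem sizes used in the tests

Unit and property tests run on small constructions (hundreds of reads,
L <= 8 exhaustive oracles).  End-to-end checks use the default study
conditions (1e5 reads per round, 3 rounds, one planted DR1-type site at
20x); the two-motif logo test uses 2 rounds with a 1e5 library and 5e4
depth so that both planted sites (30x and 10x) retain pool share and clone
artifacts stay below the weaker plant.  Null-calibration checks restrict to
estimable shape classes as described above.

## Known limitations

* Enrichment orientation is unidentifiable: reported patterns may appear as
  the reverse complement of a planted or biological motif.
* The Poisson threshold assumes independent window counts; overlapping
  windows and clone amplification make real counts over-dispersed, so the
  absolute policy is the default for exploratory tables.
* PWM extraction seeds greedily; motifs sharing substantial sequence with a
  stronger motif are absorbed into its residual rather than extracted
  separately.
* `pairwise_profile_correlation` is O(pairs x union size x model size);
  for many large tables, OMP-reduce first.
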