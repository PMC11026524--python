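# Methods

## Scope and model

m6aread implements the read-level classification and site-level
aggregation stages of a single-molecule m⁶A detection pipeline for
nanopore direct RNA sequencing. The stages upstream (basecalling, feature
extraction from the basecaller's hidden layers, genome alignment) and the
wet-lab production of synthetic training molecules are outside the
package: features and alignment records are consumed through plain data
structures, and a synthetic generator stands in for them so the entire
stack is testable offline.

Per motif i of the six targeted DRACH 5-mers, the classifier is a single
linear logistic layer P(m⁶A) = σ(w_i·x + b_i) on a feature vector x that
has been normalized by its maximum absolute value (per vector, not per
dimension across a batch). Training minimizes the sum-form binary
cross-entropy on class-balanced samples with scikit-learn's L-BFGS
(`max_iter=1000`, `tol=1e-4`). The loss is unpenalized by default, as the
objective is written; a ridge knob (`alpha`) is exposed because common
solver defaults regularize, and whether the reference models were
regularized cannot be determined from their description. Loss-internal
probability clipping uses ε = 1e-12; reported probabilities are never
clipped.

Site stoichiometry is S = (1/N) Σ Θ(P_n − 0.5) with Θ(x)=1 iff x ≥ 0, so
a read at exactly P = 0.5 counts as modified. Default reporting filters:
minimum site coverage 50; alignments with mapq strictly below 50 removed
(mapq = 50 is retained). Coordinates are 0-based half-open internally and
in BED output; 1-based coordinates appear only in labelled human-facing
text.

## Synthetic feature model

The generator emulates class-conditional basecaller features as a pair of
spherical Gaussians per (motif, class): dimension D (default 768, tests
and simulations use D = 8 — all code paths are dimension-agnostic), noise
scale `spread`, and Euclidean distance `separation × spread` between the
UNM and MOD centers. Two deliberate choices:

* **Pedestal coordinate.** Both class centers share a fixed large first
  coordinate (8 × spread). Per-vector max-abs normalization is a
  nonlinear, per-point rescaling; with a class center near the origin it
  would erase most of the class structure and decouple the `separation`
  knob from classifier difficulty. The shared pedestal makes the max-abs
  scale nearly common across points, so normalization acts approximately
  as a global rescaling and separation remains the single difficulty
  dial. This mimics the large shared activation scale of real
  convolutional features; it is an emulation, not a claim about any
  basecaller's feature geometry.
* **Separation direction** is a motif-specific random unit vector
  orthogonal to the pedestal coordinate, deterministic in
  (motif, center_seed).

What the generator does *not* model: feature correlations across
dimensions, heavy tails, sequence-context heterogeneity within a motif,
signal drift along reads. Passing tests therefore demonstrate the
correctness of the pipeline's machinery (training, calibration,
aggregation, decoding) under controlled conditions, not performance on
real nanopore data.

The calibration law E[S_measured] = (1−β)·S_true + α·(1−S_true), for a
read-level classifier with false-positive rate α and false-negative rate
β, is verified by simulation and underlies the tolerances used for
titration-slope recovery: at separation 8 the synthetic classifier's
α + β is of order 1e-4, so fitted slopes track the WT fraction to well
within ±0.03 at 3000 sites × coverage 100.

## Synthetic molecules and the chain decoder

Training molecules are concatemers of 21-nt oligos with a central DRACH
motif, in unmodified and modified variants, assembled either as
homopolymers (random ligation) or ordered heteropolymers (splint
ligation). Oligo flanks are drawn by rejection sampling so that no target
motif occurs anywhere except the designed centers, including across every
ordered junction — concatemers contain exactly the designed candidate
sites. Two benchmark designs are built in: a two-motif contrast (m⁶A on
the UGACU oligo, or flipped onto GGACC) and a periodic design — one
13-mer with central GGACU repeated with alternating modification, so m⁶A
recurs every 26 nt and a read can start on either repeat (phase 0 or
13 nt; true centers at read offsets 7, 33, 59, … or 20, 46, 72, …).

Read noise is substitution-only (rate < 0.5; indels are a declared
non-goal). Consequently the concatemer decoder matches reference oligos
by an exhaustive ungapped diagonal scan (identity threshold 0.8 by
default, match +1 / mismatch −1 scoring), which is the band-0 special
case of local alignment and exact for this error model. Matches are
chained by weighted-interval-scheduling dynamic programming maximizing
total score; adjacent hits may overlap by 2 nt to absorb junction
ambiguity, and score ties prefer the earlier-starting hit. The DP is
verified against exhaustive subset enumeration. For fragmented
read-to-reference alignments, the longest contiguous block is used
(leftmost on ties).

## Read-level evaluation

PR curves sweep descending unique scores; the AUC convention is fixed to
step-wise average precision (scikit-learn's `average_precision_score`),
with the chance baseline (positive prevalence) reported alongside. On
the periodic benchmark, each read is anchored at its highest-P(m⁶A)
position (leftmost on ties); sites at even multiples of 13 nt from the
anchor are labelled "even" (inferred modified), odd multiples "odd", and
calls are made only at the annotated candidate offsets. Reads whose call
spacing violates the period are skipped and counted. The phase offset
between the two read populations is estimated from each read's modal
residue of called positions modulo 26.

## Site-level analyses

Condition comparisons (e.g. wild type vs methyltransferase knockout) form
the joint histogram of matched-site stoichiometries in 5% bins; raw
counts are reported. Chromosome profiles bin a contig into 10000
intervals and take the per-bin median S over reported sites. Titration
analysis fits measured S against reference S by ordinary least squares
*with* an intercept — classifier false positives induce one — and reports
the slope, which estimates the WT fraction of a WT/IVT mixture.
Proximity matching against an orthogonal peak list counts predicted sites
(S above a floor, default 0.5) with a peak within 5 nt inclusive on the
same contig and strand. Per-group stoichiometry applies the same
aggregation and filters within each read group (e.g. transcript isoform);
groups below the coverage floor are suppressed even when the pooled site
passes.

## Numerical and design choices

* Balancing subsamples the majority class uniformly without replacement,
  reproducibly under a seed; already-balanced batches pass through with
  membership unchanged.
* Cross-validation shuffles once with the given seed and folds into
  contiguous blocks; k = 4 reproduces a resampled 75/25 design. Folds
  missing a class in train or validation are skipped with a warning.
  The stability experiment uses separation 2.7, which places validation
  PR-AUC near 0.97 under the feature model.
* All generators are bit-reproducible under identical seeds; derived
  seeds are spawned from `numpy.random.SeedSequence` and kept below 2³¹.
* Degenerate inputs: all-zero feature vectors pass normalization
  unchanged; empty hit lists chain to an empty, zero-score chain; an
  unaligned read has no longest segment; empty peak lists match nothing.
* Desk-scale problem sizes (chosen once for the bundled experiments):
  500 reads × 104 nt for phase recovery, 3000 sites × coverage 100 per
  titration level, 8000 samples for cross-validation, D = 8 features.

## Known limitations

The Gaussian feature stand-in cannot certify accuracy on real signal
data; the decoder does not handle indels or splice-aware alignment; no
differential-methylation testing is provided; modifications other than
m⁶A and motifs outside the six targets are out of scope.
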