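# Methods

## The assay being modeled

A domain-insertion screen inserts each motif of a donor library after
every residue of a recipient protein, expresses the variants as a pooled
single-copy library, sorts cells into a surface-labeled (high) and
unlabeled (low) gate, and sequences both gates. The phenotype is
surface-expression fitness: the log-enrichment of a variant in the high
versus the low gate, normalized to an internal flexible-linker control
(AGSAGSA). The pipeline covers five stages — synthetic data generation,
insertion calling, enrichment scoring, biophysical property computation,
and classification/modeling — each usable independently.

## Enrichment scoring

Raw scores are pseudocounted log-ratios of gate read fractions computed
within one (motif, replicate, subpool) group across positions; only
positions with reads in both gates are scored, all other cells are
explicit missing values (never silent zeros). Two deliberate conventions:

- The per-position pseudocount 0.5 enters both the numerator and the
  denominator sum (`Σ_i (0.5 + count)`), whereas the Poisson SE adds 0.5
  once to each of its four terms. The two conventions differ; both are
  kept in the form in which they are conventionally written for this
  assay rather than harmonized.
- The replicate weight is `sqrt(M + SE_r²)/Σ sqrt(M + SE_r²)`. Note this
  *up-weights* noisier replicates; it is retained as the assay's printed
  combination rule. An `weighting="inverse-variance"` mode implements the
  conventional alternative for sensitivity analysis (default off).

The between-replicate variance M is estimated per variant by REML Fisher
scoring of the random-effects model `z_r ~ N(θ, M + SE_r²)`, 50
iterations, floored at zero, initialized from the method-of-moments
estimate. Identical replicate scores give M = 0 and pass through
unchanged; the estimator is validated against an independent scalar
transcription in the test suite. Control z-scoring uses the sample
standard deviation (ddof = 1) of the control motif's raw scores, scoped
per (subpool, batch) by default and globally on request; scopes with
fewer than 2 control scores or zero spread are rejected with a warning
and their scores left missing. Motifs observed at a fraction of positions
not strictly greater than 0.8 are dropped from the fitness matrix.

## Synthetic screen generator

The generator emulates the statistical structure of the two-gate assay,
not its molecular detail. Defaults define the study conditions used
throughout the tests: 50 recipient positions x 39 motifs + control, two
replicates, one subpool, 10^5 reads per gate and replicate, 4x10^4 cells
per gate (20x variant coverage, the middle of the coverage range typical
for such screens), 5% per-replicate variant dropout, lognormal (sd 0.3)
library abundance drawn once per screen.

- Ground truth: positions carry one of three classes (rigid /
  intermediate / flexible) in contiguous blocks with seed-randomized
  boundaries, mirroring contiguous structural regions; motifs carry one
  of three groups (structured / unstructured / hydrophobic). True fitness
  is class + group main effects + interaction + Gaussian noise (sd 0.5).
  Default effects plant a rigid x structured incompatibility and a
  flexible x structured bonus. The control motif's true fitness is 0 by
  definition — it is the normalization anchor.
- Sorting: P(high gate) is logistic in true fitness (the minimal monotone
  link for a two-gate sort; the assay itself specifies none). Cells are
  multinomial over variants within each subpool and gate; reads are a
  second multinomial over the sampled cells. Dropout zeroes counts after
  sampling, so totals after dropout are bounded by the configured depth.
- Reads: each count unit yields one pair spanning the insertion, the
  forward mate across the upstream recipient/motif junction and the
  reverse mate (reverse-complemented) across the motif/recipient
  junction, each with >= 20 matching nt flanks; read names encode the
  ground truth for assertions. Fragment placement and substitution errors
  use independent RNG streams, so the same seed with a different error
  rate perturbs the same fragments.

What the generator does *not* emulate — PCR jackpotting and chimeras,
instrument error profiles, quality-score variation, selection-step
artifacts — bounds what passing tests show about real data: they verify
the statistics and the code paths, not robustness to those artifacts.

## Insertion calling

Seed-and-extend exact matching against the recipient CDS flanked by its
vector context: the longest exact reference-matching prefix (and,
symmetrically, suffix) of each read defines a candidate junction; the
intervening segment must match a known motif (fully, with the read's
remainder matching the reference at the junction, or as a motif
prefix/suffix) with both flanks >= `min_flank` (default 15 nt). Junction
microhomology — a motif boundary base coinciding with the adjacent
recipient base — shifts the maximal extension past the true junction, so
placements are backed off by up to 12 nt, preferring the placement that
identifies a known motif; below `min_flank` only full-motif evidence with
a long opposite flank is accepted. Inserts matching no motif are called
with `motif_id="unknown"`; multiple equally good placements refuse to
call and are logged as ambiguous. Positions are 1-based "after residue
i"; `aa_position = junction_nt // 3` with `in_frame = (junction_nt % 3 ==
0)`, so junctions inside a codon report the preceding residue, out of
frame. Concordant mate pairs count once; discordant pairs are dropped and
counted. Only in-frame calls enter the count table (out-of-frame calls
are tallied separately), matching the gating step that removes
frameshifted variants. Substitution errors are tolerated only outside the
matched windows; this exact-match caller is intended for desk-scale
synthetic data and makes no claim to replace a production aligner.

## Biophysical properties

- **ANM**: standard anisotropic network model on Calpha coordinates,
  cutoff 15 A, spring constant gamma = 1 (both configurable; the cutoff
  is a common default for Calpha ANMs). A connected network has exactly
  six rigid-body zero modes (relative threshold 1e-8); degenerate
  geometries (collinear/planar bead sets) produce more and are rejected
  where profiles would be meaningless. Stiffness: for each residue pair,
  the reciprocal of the mode-sum compliance along the inter-residue unit
  vector (`e^T (C_ii + C_jj - C_ij - C_ji) e`, C the pseudo-inverse
  Hessian), averaged over partners. Fluctuations: trace of the diagonal
  3x3 block of C, normalized to mean 1, serving as an RMSF surrogate;
  molecular-dynamics RMSF is only ever an *input* (annotation CSV), never
  computed.
- **Sequence windows**: 14 published residue scales (hydropathy is
  Kyte-Doolittle; see `scales.py` for all sources). Recipient features
  are window sums of lengths 1/3/5/7/9/11 anchored before, centered on,
  and after the insertion site; motif features are whole-sequence sums
  plus N-/C-terminal sums of lengths 1-6, plus motif length. Windows
  truncated at the termini sum over the available residues and are
  flagged. Which residue-level table the original scale names refer to is
  not fully standardized; the shipped tables are the cited standards.
- **Contact density**: inter-residue heavy-atom pairs within 4.5 A
  (sequence separation >= 2). This is a plain distance-cutoff count, a
  documented simplification of SMARTS-typed contact detection.
- **Backbone/surface**: phi/psi from the backbone (degrees, (-180, 180]),
  SASA by Shrake-Rupley (probe 1.4 A, element radii) split into polar
  (N/O) and nonpolar atoms; secondary-structure content comes from an
  annotation file or stays missing — no DSSP reimplementation.
- **Assembly** joins per-source frames on position/motif keys, rejecting
  duplicate feature names and unmatched keys; absent sources yield absent
  columns, not NaN-filled ones.

## Classification layer

Motif clustering: cosine distance on positional profiles with missing
cells excluded pairwise (pairs with < 2 shared observations or a zero
profile get distance 1), Ward linkage, cut at 3 groups by default.
Position classification: missing cells are imputed with the per-motif
mean (the natural center given control-anchored z-scores; a row-dropping
alternative exists), a 2-D UMAP embedding (cosine metric by default,
neighborhood 10, fixed seed) is labeled by k-means (20 restarts) for k in
2..8, and the consensus k is the majority vote of silhouette,
Calinski-Harabasz, Davies-Bouldin, Dunn, and the gap statistic (10
uniform bounding-box references), ties toward smaller k. Five indices
are enough for a stable majority and each is implemented directly; how
labels are extracted from an embedding is genuinely open, and k-means on
the embedding is the decided mechanism. Fisher's exact test sums
hypergeometric probabilities of tables at the observed margins with
probability <= the observed one (a 1e-9 relative guard absorbs floating
noise); odds ratios use the Haldane-Anscombe 0.5 correction when a cell
is zero. Cramér's V is `sqrt(chi2 / (n (min(r,c) - 1)))` on the
uncorrected chi-squared. The terminal analysis counts productive cells
(score above a threshold, default 0 = better than the flexible-linker
average) in the first/last 45 positions against the window-size
expectation.

## Compatibility model

Features are reduced by grouping |Pearson rho| >= 0.8 (transitive
closure; chaining is a deliberate choice — the relation is not itself
transitive) and keeping the member with the largest summed |correlation
with the response| (optionally summed within row groups, e.g. per
position). The forest is a 500-tree regression random forest, mtry = p/3,
unlimited depth, fit on a seeded 85% split with 15% held out; variance
explained is reported on the held-out set and out-of-bag. Importance is
drop-and-refit: each feature is removed, the forest refit with the same
seed and split, and the held-out MAE increase recorded (negatives clipped
in the ranked column only). ALE uses the quantile-bin estimators
(first order: accumulated within-bin prediction differences, centered to
data-weighted zero; second order: accumulated cross-differences minus
both first-order components and the constant; empty 2-D cells filled from
the nearest non-empty cell and flagged). Interaction strength is
Friedman's H from brute-force partial dependences on a seeded sample
(default min(500, n) points), centered, reported as H in [0, 1] with
excursions clipped and flagged. All three interpretation statistics are
validated against closed forms (linear slope, additive H = 0,
multiplicative H = 1 with independent mean-zero features).

## Problem sizes and numerical choices

The default test-suite and acceptance problem sizes are 50 x 40 variants
at 10^5 reads/gate for recovery, 10^4 read pairs for calling, a 10-bead
helical chain and 12-point cluster for ANM contracts, 3,000-point oracle
sets for ALE/H, and n = 2,000 (five seeds, noise sd 0.5) / n = 6,000
(noise-free) for the model benchmark — sizes chosen so each check is
statistically decisive at desk scale. Ties in the consensus vote go to
the smaller k; REML uses 50 iterations from a moments start; windows at
termini truncate-and-flag rather than dropping positions.

## Known limitations

The caller assumes exact flank matches and a unique junction; it is not a
production aligner. The ANM stiffness formulation follows the standard
mechanical-stiffness mode sum; published per-protein stiffness values
computed with other codes may differ by scale. The generator's planted
effects are block-additive with a single interaction structure, far
simpler than real position-motif coupling. Secondary structure and MD
RMSF are inputs, not computed. The forest benchmark measures recovery of
planted signal, not predictive performance on any real screen.
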