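# Methods

This note documents the statistical model behind `kosig`, the conventions
the implementation fixes where the method leaves room, the synthetic data
generator, and known limitations.

## Data model

Per sample (a parental clone or a subclone), each mutation class is reduced
to a channel-count vector: 96 substitution channels (pyrimidine-context
trinucleotide types), 8 indel channels, 10 rearrangement channels. Parental
clones provide the matrix M_p, the knockout's subclones M_s; subclone
records are assumed to be de novo (parental-subtracted) before cataloguing.
Parental subtraction matches substitutions and indels on exact
(chrom, pos, ref, alt); rearrangements match when svclass and chromosomes
agree and both breakpoints lie within a tolerance (default 500 bp,
reflecting breakpoint imprecision of split-read callers; configurable). The
same operation filters parental clones against the bulk population.

### Channel conventions

* Substitutions are represented in pyrimidine context: purine-reference
  records are reverse-complemented (context included) before labelling.
  Records with N in the trinucleotide context are excluded and counted in a
  reject report.
* Deletions are left-aligned against the reference before junction analysis.
  A deletion is repeat-mediated when at least one full additional copy of
  the deleted motif lies immediately 3' of the (left-aligned) deletion;
  otherwise microhomology-mediated when the deleted motif's 5' end shares at
  least 1 bp but less than its full length with the sequence immediately 3'
  (defined only for deletions ≥2 bp, split at 2 bp vs ≥3 bp); otherwise
  "other". Repeat-mediated takes precedence over microhomology, mirroring
  standard indel-signature practice; microhomology is scanned only at the 3'
  junction — a single deterministic convention. A non-repeat 1 bp deletion is
  "other" (no 1 bp microhomology channel exists).
* Rearrangement spans (pos2 − pos1) are binned [1 kb, 10 kb],
  (10 kb, 1 Mb], (>1 Mb]; spans below 1 kb are rejected as below calling
  resolution rather than force-binned. Translocations are exactly the
  inter-chromosomal records.

## Step 1 — spectrum-shift test

All profiles are compared in unit-sum (proportion) space with the Euclidean
(Frobenius) norm, which makes distances comparable across samples with
different burdens; raw count-space distances are available behind
`normalize=False` for sensitivity analysis.

Each parental clone is bootstrapped by multinomial resampling (replicate
size = the clone's total, probabilities = its proportions), 7000 replicates
per clone, pooled across *all* parental clones (nine clones give a 63,000
replicate pool). 10,000 rounds each draw 7 distinct replicates from the
pool and record the distance from their normalized-centroid to the centroid
of the original parental clones; the empirical floor-rank (1−α) quantile of
these distances is d_pc,α. The same construction per knockout (9000
replicates per subclone, draws of 9) gives d_sc,α. The parental threshold
is therefore global across knockouts while the subclone threshold is
per-knockout. The draw sizes of 7 and 9 look swapped relative to the group
sizes (9 parental clones, 7 subclones) but are kept as published; both are
configurable. A knockout is *shifted* when the observed centroid distance
d_ps strictly exceeds both thresholds; ties are non-shifted.

Default sizes are the published ones (7000/9000 replicates, 10,000 distance
rounds, α = 0.01). The evaluation studies in `kosig.studies` run at reduced
sizes (1000 replicates per sample, 2000 distance rounds) — the package's
own choice of study problem size; at the effect magnitudes studied the
decisions are indistinguishable from full-size runs.

## Step 2 — count-elevation test

The baseline pool holds the per-subclone de novo totals of every knockout
without a spectrum shift (per mutation class — a knockout can be baseline
for rearrangements while shifted for substitutions). Each of n_boot
(default 10,000) bootstrap aggregates sums n_target draws with replacement
from the pool; the p-value uses the add-one estimator
p = (1 + #{aggregate ≥ observed}) / (1 + n_boot), so it is never exactly
zero. The final call is the strict conjunction: has_signature ⇔ shifted and
p < α. No multiple-testing correction is applied across knockouts. If every
knockout is shifted the baseline is empty and the pipeline reports an
instructive error (an external baseline of per-subclone totals can be
supplied).

## Step 3 — background exposure and signature extraction

The subclone centroid spectrum is modelled as
M̄_s ≈ e_p·P̄_p + e_ko·P_ko, with P̄_p the *pooled* parental profile
(clones weighted by their totals, not an average of proportions). The
centroid total is the rounded mean of subclone totals, keeping e_ko
interpretable per subclone and giving per-division rates directly as
e_ko / divisions (~36 divisions in the one-month design).

Per-channel boundaries come from a multinomial bootstrap of the centroid
(10,000 replicates of size = centroid total with centroid proportions);
lower/upper bounds are the outer order statistics of the 99% CI (outward
rounded). Starting at e_p = centroid total and decrementing by 1, each
candidate draws 100 multinomial background profiles of size e_p from P̄_p
and stops at the first e_p where at least 5 profiles are compatible with
the boundaries.

**Compatibility is one-sided by design.** A profile is compatible when
every channel count is ≤ the upper boundary. The background component of a
channel can never exceed what the subclone spectrum accommodates, but it
may legitimately fall below the lower boundary wherever the knockout
process contributes the remainder — requiring the two-sided interval in
every channel would make the search unsatisfiable whenever P_ko has support
the background lacks (the background can never reach the lower bound of a
knockout-dominated channel), driving e_p to 0 in exactly the cases the
method exists for. Lower boundaries are still computed and can be enforced
(`enforce_lower=True`) for diagnostics on null-like data.

Two properties of this stopping rule are worth knowing:

* It is *conservative upward*: it returns the largest e_p compatible with
  the subclones at the 5% acceptance level, i.e. an upper confidence bound
  on the background. In simulations at study-scale counts (background 1200,
  knockout exposure 3600) the recovered e_p overshoots the generating
  background by roughly 20–25% (the overshoot scales like the upper-bound
  slack of the most loaded background channel divided by its weight, so it
  shrinks with total mutation count). Consequently e_ko is slightly
  underestimated (by a few percent when e_ko ≫ e_p) — a bias in the safe
  direction for claiming knockout mutagenesis — while the extracted
  *profile* is essentially unaffected (cosine to truth ≥ 0.99 in the strong
  scenario).
* Candidates are evaluated in fixed descending order against a single RNG
  stream (drawn in vectorised blocks), so a given seed always reproduces
  the same e_p, and widening boundaries can only increase it.

The signature is the residual M̄_s − e_p·P̄_p with negative channels
clipped to zero, renormalised to unit sum (the subtraction formula can go
negative and prescribes no rule; clipping preserves non-negativity).
e_ko = centroid total − e_p exactly, and extraction refuses to run when
e_ko = 0 (callers should gate on has_signature).

## Similarity and topography

Extracted signatures are compared to reference channel × signature matrices
by cosine similarity; reports keep all cosines (runner-up similarities are
informative when several related reference signatures score highly). Since
published reference catalogs cannot be redistributed here, the package
generates synthetic stand-in catalogs (sparse Dirichlet columns, optionally
embedding known profiles); the loader accepts any conforming TSV, so real
catalogs can be dropped in.

Strand analyses first flip every substitution to its pyrimidine
representation. In transcription mode a pyrimidine lying on a gene's own
(coding) strand is "untranscribed", on the template strand "transcribed";
overlapping opposite-strand gene annotations yield "unassigned" (counted,
not guessed). In replication mode the annotation gives the leading/lagging
orientation of the + reference strand and the pyrimidine strand selects the
label. Asymmetry per substitution type is tested with a two-sided *paired*
t-test on per-subclone strand counts (the natural pairing of the two counts
within a subclone); the test variant is a package choice, and counts-level
alternatives can be computed from the returned per-subclone table. Timing
densities are per-decile counts divided by decile genomic length, scaled so
the ten-decile mean is 1.

## Synthetic data generator

The generator emulates the experimental layout: nine parental clones and
seven subclones per knockout. Sample burdens follow a negative binomial
with mean 1200/60/6 (substitutions/indels/rearrangements) and coefficient
of variation 0.15, matching the background levels and tight between-subclone
consistency the design exhibits (Poisson when the target variance does not
exceed the mean, as for rearrangement-scale counts). Channel counts are
multinomial in the background profile; subclones add an independent
multinomial knockout component of size e_ko. The default substitution
background concentrates 74% of its mass on C>A channels with peaks
T[C>A]T > G[C>A]A > G[C>A]T > A[C>A]A, echoing the culture background;
named scenarios provide mismatch-repair-like (C>T/T>C, 3× background),
exonuclease-like and crosslink-repair-like effect profiles. All scenario
profiles and exposures are package choices documented in
`kosig.simulate`; they were fixed from the stated study conditions, not
tuned.

Record-level simulation places each drawn channel on a deterministic toy
genome (default: one 1 Mb random contig with planted poly-A and CAG repeat
tracts, 10% gene coverage on alternating strands, alternating 50 kb
leading/lagging blocks, ten equal timing deciles; evaluation studies use a
200 kb contig). Sites are chosen from precomputed per-channel site indexes
and every emitted record is verified to classify back to its channel, so
catalog reconstruction is exact by construction. Rearrangement breakpoints
live on declared coordinate-only contigs (6 Mb), since rearrangement
classification never consults sequence.

What the generator does *not* emulate: mutation accumulation through the
lineage (exposures are drawn per sample, matching end-point catalogs),
calling errors and coverage-dependent sensitivity, clustered or kataegic
mutations, sequence-context biases of real genomes beyond the planted
tracts, and correlated noise between channels. Passing tests therefore
demonstrate the statistical machinery under the stated generating model,
not robustness to caller artefacts.

## Numerical choices and degenerate inputs

* Empirical thresholds use the floor-rank order statistic of the sorted
  distance distribution; quantile ties therefore resolve downward.
* Zero-total samples cannot be normalized or bootstrapped and raise
  explicit errors; empty samples are allowed in catalogs as zero vectors.
* The add-one p-value floor is 1/(1 + n_boot).
* Signature weights renormalise when they deviate from unit sum by more
  than 1e-9; columns of loaded reference catalogs are always renormalised.
* Within-round bootstrap draws are without replacement (duplicate rounds
  are redrawn), matching the "select k replicates" construction.
* Seeds propagate through `numpy` Generators; every pipeline stage derives
  its stream from the run seed, so reports regenerate bit-identically.

## Limitations

* One background plus one knockout component; no NMF-style multi-signature
  deconvolution.
* The e_p estimator is an upper confidence bound, not an unbiased point
  estimate (see above); treat e_ko as a mild lower bound at small totals.
* Real reference catalogs (COSMIC substitution signatures, rearrangement
  signatures) must be supplied by the user as TSVs; shipped comparisons use
  synthetic stand-ins.
* Replication-strand annotations are consumed as prepared orientation
  tracks; deriving orientation from raw Repli-seq waveforms is out of
  scope, as are variant calling, liftover and multi-sample VCF genotype
  semantics.
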