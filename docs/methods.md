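# Methods

This note documents the models implemented in `selindel`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Inter-gap segments and stratification

A pairwise alignment block is scanned for indel evidence: a maximal run of
consecutive gap columns — in either row, including runs that alternate
between rows with no intervening match column — counts as **one** indel
event (fragmented gap placement within one event would otherwise inflate
short-IGS counts).  The gap-free runs between consecutive events are the
internal inter-gap segments (IGSs), measured in reference bases.  Runs
touching a block boundary, an excised interval, or an assembly-gap guard
(≥ 10 consecutive `N` columns) have unobserved full length; they are
flagged *censored*, counted toward aligned footprint, and excluded from all
fitting and excess summation.  Dropping right-censored observations is
conservative and avoids the bias that thresholding censored lengths would
introduce into overhang expectations.

Segments are stratified into equally populated regional-G+C bins (default
20; quantile binning with a stable (gc, chromosome, position) tie-break, so
populations differ by ≤ 1) plus one X-chromosome stratum.  G+C is measured
on a fixed 100 bp ungapped-reference window centred on the segment.  The
fixed width matters: measuring G+C on the segment's own bases makes its
sampling variance depend on segment length, and quantile binning then
sorts short segments into the outer bins, distorting each bin's length
distribution and the geometric fits downstream.  Regional G+C with constant
variance keeps binning orthogonal to length.

Coordinates are 0-based half-open throughout, including BED I/O; MAF/AXT
conventions are translated at the file boundary and query starts stay
strand-relative (MAF-native), which keeps sub-block coordinate arithmetic
uniform when blocks are trimmed or split.

## Alignment trimming

A 4×4 log-odds substitution matrix is estimated from the alignment itself:
score(a,b) = s·ln[f(a,b)/(f_ref(a)·f_qry(b))] over non-gap columns with a
pseudocount of 1 per cell (avoiding infinite scores for unobserved pairs),
in half-bit units (s = 2/ln 2, configurable).  No symmetry across strand or
species is imposed.  Gap penalties derive from the observed gap spectrum:
gap-open from the per-column event rate, gap-extend from a geometric fit to
gap lengths (floored when all gaps have length 1).

Trimming removes, per block: (1) the maximal non-positively scoring
terminal segments — the prefix cut maximising the remaining score, ties
resolved toward the longer cut, then the same from the right; (2) every
non-positively scoring internal inter-gap segment, splitting the block.
Internal segments are scored without the delimiting gap events' costs (the
gaps delimit; charging them to the segment would double-penalise).  Newly
exposed ends are re-trimmed, so the output is a fixed point: every emitted
sub-block has positive total score and positively scoring ends, and
trimming is idempotent.  Terminal trims take precedence over internal
deletions; matrix estimation is a single pass (no re-estimation after
trimming).  On constructed blocks with unrelated random flanks around a
homologous core, trimming removes ≥ 95% of flank columns and < 5% of core
columns.

## NIM1: regression estimator

For each stratum, ln(count) is regressed on length by weighted least
squares (weights = counts, zero-count lengths skipped) over a fit window
chosen in two passes: a provisional decay rate θ₀ = 1/mean(x) anchors the
window [0.25/θ, 2K], re-anchored once on the refitted slope.  The window
deliberately ends near 2K because segments containing a constrained core
begin to appear just above two neutral overhangs; letting them into the
window flattens the slope and inflates the extrapolated neutral tail.
Fixed absolute windows are not usable — the IGS length scale varies
severalfold over the divergence range of interest.

Two quantities deliberately do **not** come from the regression slope:

* **K**, the neutral overhang, uses the memoryless moment estimator
  E[x − L_lo | x ≥ L_lo], which equals (1−θ)/θ under the geometric law but
  pools the entire upper histogram and is an order of magnitude less
  variable than the slope.  Contamination by constrained segments only
  enlarges K, making the lower bound more conservative.  (With an explicit
  user-supplied fit range the classic closed form K = (1−θ)/θ is used
  instead.)
* **T**, the excess threshold, is 2K + 40 bp.  Segments below 2K contribute
  nothing after overhang subtraction in any case, and the 40 bp margin
  keeps the detection floor comparable across divergences while leaving the
  lengths where neutral-fit uncertainty dominates out of the excess sum.

The constrained amount is the **netted excess**

    α (bp) = max( Σ_{x>T} [ c(x) − ê(x) ] · max(x − 2K, 0), 0 )

summed over the full integer tail — zero-count lengths contribute −ê(x),
and the analytic geometric remainder beyond the last observed length is
subtracted.  Netting is essential: flooring each length's excess at zero
turns symmetric Poisson noise into a positive bias of order √N per length,
which at realistic histogram sizes overwhelms the signal (measured ≈ 1% of
aligned bases on fully neutral data).  With netting, fully neutral input
yields α = 0.

Two corrections to the derivation are known to act in opposite directions:
conditioning on exceeding the threshold lengthens the expected overhangs
(deflating the estimate if corrected), while constrained segments deplete
the neutral background (inflating it).  Their effects approximately cancel,
so the default estimator applies neither; a fixed-point depletion
rescaling of ê by (1 − α) is available (`depletion=True`) for sensitivity
analysis and raises estimates by roughly α × (neutral tail)/total.

The 95% CI is a parametric bootstrap (default 1000 draws, seeded) of
(intercept, slope) from the regression covariance, propagated through the
full netting computation; K and T are held fixed at their moment-anchored
values.  Per-stratum estimates are summed; stratum variances combine in
quadrature under independence.

Constraint inside an annotation subset S is estimated by difference:
α(S) = α(G) − α(G∖S), with S (plus a buffer, default 50 bp) excised from
the blocks — segments abutting an excision become censored ends — and the
CI combined in quadrature.  The direct-difference route is required because
S itself is usually not dominated by neutral sequence, so the neutral fit
inside S would be meaningless.

## NIM2: likelihood estimator

Internal IGS lengths follow a two-component mixture: neutral-geometric(θ)
with probability 1 − π, else the sum of a geometric constrained core
(mean μ_c) and two independent neutral overhangs (geometric, same θ).  The
component is computed by FFT convolution on the integer support up to the
observed maximum; (θ, π, μ_c) maximise the multinomial log-likelihood
(Nelder–Mead on logit/log-transformed parameters, initialised from the
NIM1 geometric fit, π₀ = 0.01, μ₀ = 200).  α = π·N·μ_c.  The 95% CI
profiles the likelihood over ψ = π·μ_c (bisection to Δlog L = 1.92); a
faster Wald interval via a finite-difference Hessian is used when strata
are aggregated.  At the π → 0 boundary the estimate is reported as 0.

NIM1 and NIM2 agree within ~5–10% on simulated data across divergences
0.15–0.6; NIM2 is close to unbiased while NIM1 sits a few percent below
truth by construction.

## Divergence

Neutral divergence is estimated from ancestral-repeat columns (non-gap,
non-N, reference position inside a repeat annotation) as the ML distance of
an unrooted sequence pair under HKY85: empirical base frequencies pooled
over both sequences and held fixed, rate matrix normalised to one expected
substitution per site per unit time, likelihood from the 4×4 pair-count
matrix with P(d) = e^{Qd}, optimised over (ln d, ln κ) to tolerance 1e-8.
Reversibility makes the likelihood symmetric in the two sequences.  A
single rate class is used (no gamma variation).  With equal base
frequencies the estimate matches the Kimura two-parameter closed form to
1e-4.  The median-dS utility discards saturated genes (dS ≥ 1) and takes
the median of the rest; codon-model estimation itself is out of scope.

## Turnover model

For an element class with constant total amount *a* and per-nucleotide
turnover rate *b* (events per neutral substitution), the mutually
constrained amount at divergence *d* is a·e^{−bd}.  Fitting is weighted
linear regression of ln(amount) on d (the only linear formulation of the
model): slope = −b, intercept = ln a.  Observation weights are inverse
variances of the amount on the natural scale — by default (1.96/half-CI)² —
moved to the log scale by the delta method (w_log = w·amount²); unit
weights when no uncertainty is supplied.  CIs are t-based from the weighted
fit; a slope of the wrong sign floors b at 0 with a diagnostic flag rather
than a constrained re-fit (transparency over silent constraint).  Empirical
coverage of the b interval is 93–97% over seeded lognormal-noise
replicates.

Conversions: d½ = ln 2 / b (infinite at b = 0, flagged); years = d / r with
r = 2.2×10⁻⁹ substitutions/site/year by default (appropriate to the human
lineage; rodent lineages are faster and r is overridable); the age of the
common ancestor is d/(2r) since divergence accumulates on two branches.
The d½ CI transforms the b CI directly; this can differ in the last
printed digit from intervals derived by other routes (≤ 0.01 here).
Present-day totals across annotation classes sum per-class *a* with CIs in
quadrature; the independence assumption is stated in the output, and
overlapping class labels draw a warning because the decomposition is only
meaningful for mutually exclusive sets.

Rate comparison between two classes fits a shared-slope model (common b,
separate intercepts) against independent slopes by weighted least squares.
Weights are treated as exact inverse variances, so the likelihood-ratio
statistic is the drop in weighted RSS referred to χ²(1) — exactly
calibrated under the null when weights are correct (verified by KS
uniformity over seeded null datasets), approximate when weights are known
only up to scale.

## The simulator

The generator emulates the statistical structure the estimators assume,
with full knowledge of the truth:

* **Ancestor**: i.i.d. bases at 41% G+C; constrained elements with
  geometric lengths (mean 200 bp) totalling 5% of the sequence by default,
  placed uniformly without overlap, or clustered (each next element within
  one mean length of the previous, with the configured probability).
* **Substitutions**: each lineage evolves d/2 substitutions per site as an
  exact HKY85 CTMC (κ = 2.5) realised by uniformization, so realized event
  counts — not approximations — are recorded; constrained sites substitute
  freely, because the constraint being tested is on indels only (a
  substitution-constraint switch would confound the validation).
* **Indels**: 0.1 events per substitution at neutral positions, insertions
  and deletions equiprobable, lengths from a truncated power law (exponent
  1.6, max 50 bp; geometric alternative available).  Events whose footprint
  intersects a constrained element at event time are re-drawn.  The
  mammalian indel/substitution ratio and spectrum motivate these defaults.
* **Turnover**: whole elements relocate at rate b per unit divergence,
  keeping the constrained amount constant in expectation; relocation
  targets are unconstrained, insertion-free windows (prior deletions are
  allowed — surviving bases remain contiguous in the extant genome).
* **Bookkeeping**: each branch runs in 100 discrete epochs so indels,
  turnover and the constraint mask interleave correctly; all randomness
  flows from one seeded generator, and a fixed seed reproduces the output
  byte-for-byte.  Because every event lives in ancestral coordinates, the
  emitted alignment is the *true* column map, and element truth is
  reported in both extant genomes' coordinates.

What the generator does **not** emulate: sequence-context-dependent
mutation (CpG), regional rate variation and real G+C heterogeneity,
alignment error (blocks are true alignments — the trimmer is therefore
validated on constructed decoys, not on simulator output), transposon
insertion, segmental duplication, and selection on substitutions.  Passing
tests on this generator show the estimators are correct *under the model's
own assumptions*; they do not certify behaviour under alignment artefacts,
which on real data are handled by the trimming stage.  Indels are placed in
ancestral coordinates and inserted material receives no secondary events —
a second-order approximation at the divergences simulated (≤ 0.6).

## Validation summary and problem sizes

Simulation-based checks run at 4–10 Mb (grid runs; the published-scale
analogue of this validation used 200 Mb genomes, and estimates scale
linearly with genome size).  At 10 Mb the NIM1 per-run standard deviation
is ~1.5% of truth at divergence 0.6 and ~6% at 0.15.  Measured behaviour:
fully neutral input gives α = 0; across the divergence grid NIM1 averages
0.95–0.98 of truth (conservative in the mean, individual runs within noise
of truth); estimates under a no-turnover scenario are flat in divergence
(range/mean < 15%); doubling element clustering moves estimates < 5%; the
turnover fitter recovers b = 2.48 within 0.5% on average from synthetic
decay data.  The acceptance script reports the scaled-to-3 Gb grid mean
(≈ 145 Mb against a 150 Mb scaled truth) and the mean recovered b.

## Known limitations

* α_selIndel is a lower bound by design: sub-threshold elements are
  invisible, and each detected element is debited two full overhangs.
* The α fraction is relative to *aligned* bases; genome-wide Mb totals
  require an explicit scaling choice by the caller.
* NIM1's variance at low divergence (< 0.2) is dominated by extrapolation
  of the neutral tail; strata should not be made smaller than ~10⁴
  segments.
* The turnover model assumes one rate per class and constant total amount;
  class heterogeneity biases d½ toward the fast end.
* compare_rates p-values are exact only when observation weights are true
  inverse variances.
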