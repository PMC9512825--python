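# Methods

This note documents the statistical model behind `breakclust`, the choices
made where the design was genuinely open, what the synthetic cohorts do and
do not emulate, and the package's known limitations.

## Breakpoint proximity

All breakpoints of a cohort are pooled per chromosome — a coordinate
present in two donors is counted twice, so recurrence accumulates mass.
Neighbor reachability `bpnr_i` is the mean distance to the two flanking
breakpoints; the first and last breakpoint of a chromosome use their single
available neighbor, keeping the output aligned one-to-one with the input
rather than discarding telomeric signal. The proximity transform
`bpp = −log10(bpnr + 1)` maps distance 0 to 0 and grows more negative with
sparser breakpoints; multiplying all spacings by 10 shifts it by −1.

The proximity curve is a LOESS fit to the `(position, bpp)` scatter:
degree 2, tricube weights over the `⌈α·n⌉` nearest points (α = 0.2 of the
chromosome's breakpoints), no robustness iterations, evaluated at the
breakpoint positions themselves. Because the window is a *point* fraction,
its genomic width adapts: it narrows inside dense clusters, which is what
lets the curve express sharp summits at hotspots. Chromosomes with fewer
than 100 breakpoints cannot support a reliable curve and are excluded from
modeling and peak calling (their counts are logged). Zero-length windows
(all points coincident) fall back to the weighted mean; the local quadratic
solve is ridge-stabilized at 1e−8 after scaling distances to O(1).

## The background model

The expected curve is a penalized Gamma GLM with identity link on
per-breakpoint covariates:

* linear factors: fragile site (binary), LAD (binary), repeat class
  (11 levels, reference `none`), chromatin state (15 levels, reference
  `Quies`);
* penalized splines of replication timing, GC content, gene density, TAD
  recurrence and TAD-boundary recurrence, each duplicated per LAD level
  (factor-by construction);
* tensor-product interactions (gene density × TAD recurrence),
  (gene density × RT), (RT × TAD recurrence), duplicated per TAD-segment
  class (quiescent / low-active / active).

**Response sign.** Proximity values are ≤ 0 while a Gamma response must be
positive, so the model is fitted to `y = max(−bpp, 0) + 1e−6` and
predictions are reflected back. This is a monotone reflection; the curve's
shape is untouched. The small floor also absorbs any slight positive
overshoot the smoother can produce near very tight clusters.

**Basis.** Smooths are cubic B-splines with knots at data quantiles and a
second-order difference penalty, default basis dimension 10 (5 per tensor
marginal), each basis sum-to-zero constrained against the intercept.
Tensor bases are row-wise Kronecker products of the constrained marginals
with penalty `S₁⊗I + I⊗S₂`. Variables with very few distinct values drop
to a linear spline automatically. Penalized B-splines were chosen over
thin-plate splines for numerical simplicity at 1-D marginals; at these
basis dimensions the two families are practically interchangeable.

**Fitting.** Penalized IRLS; for the identity link the working response is
`y` itself and the weights are `1/μ²`. Steps are halved as needed to keep
fitted values positive; convergence is a relative deviance change below
1e−7 (cap 200 iterations).

**Smoothing-parameter selection.** The smoothed response is strongly
serially correlated along each chromosome, and pointwise criteria (GCV,
REML) then select near-zero smoothing: a fit that memorizes one
chromosome's curve looks excellent to them while destroying the
signal/background separation. The default is therefore
**chromosome-blocked cross-validation** on the IRLS working model: whole
chromosomes are held out (3 folds, round-robin), each candidate
`(λ_smooth, λ_tensor)` costs one linear solve per fold, and the selected
point is the *heaviest* smoothing whose held-out error is within 5% of the
minimum (a `lambda.1se`-style parsimony rule; fold noise otherwise favors
wiggle). Fold systems carry a 1e−8 ridge so a factor level confined to
held-out chromosomes cannot make them singular. Single-chromosome data
fall back to GCV with an effective-df inflation factor of 1.4.

**Robustness.** The background model must not learn the candidate loci it
exists to expose. The fit is therefore robust by default: Huber weights
(c = 1.5) on Gamma Pearson residuals with MAD scale. Crucially, the
weights are anchored on a *heavily smoothed pilot fit* — residuals judged
against a flexible fit would be masked, because the flexible fit chases
the outlying loci first. One further reweighting against the final fit
(taking the elementwise minimum with the pilot weights) refines the result
without reopening that loophole.

**Inference.** Explained deviance is `(D_null − D_res)/D_null` with the
intercept-only Gamma deviance as the null. Per-term Wald tests use the
Bayesian posterior covariance `(XᵀWX + S_λ)⁻¹·φ` (φ from the Pearson
statistic); a singular block reports a missing p-value. Partial effects
are evaluated on grids with ±2 SE bands; tensor terms on a lattice.

Missing numeric covariates are imputed to the training median and counted;
positions outside a factor track take its declared reference level, and
positions outside a binary track's intervals are the value 0, not missing.
Breakpoints outside all TADs get recurrence 0 and class `quiescent`.

## Derived 3D-genome covariates

TAD recurrence of a query domain is the fraction of panel samples having a
single TAD that overlaps ≥ 70% of the query's own length (the query length
is the denominator, so nested calls still count). The genome is then cut
at every TAD endpoint into runs of constant recurrence (overlaps take the
maximal value; adjacent equal runs merge). TAD boundaries are 50-kb
intervals centred on TAD endpoints (the width is configurable — no
canonical value exists) with recurrence computed by the same rule.
Segments are classified by their 15-state chromatin coverage: PCA to three
components, k-means with k = 3 (fixed seed), clusters named by mean
coverage (highest Quies+Het → quiescent, highest TssA+Tx+Enh → active,
remainder low-active); fewer than three segments use a direct coverage
rule. GC is computed over 101-bp windows centred on the breakpoint (Ns
excluded from the denominator), gene density as the count of genes
overlapping the breakpoint's 1-Mb bin (a gene spanning two bins counts in
both).

## Peaks, null and candidates

The adjusted curve (observed − expected) is segmented at zero crossings;
in each positive excursion the peak region is the maximal run around the
summit with values ≥ 75% of the summit height, with region edges placed by
linear interpolation at the exact threshold crossing — this keeps narrow
summits at a positive genomic range and reproduces closed-form geometry
(a unit triangle over [0, 1000] yields region [375, 625]) independent of
the discretization. `Peak_A` is the trapezoidal integral of the adjusted
curve over the region (per-Mb units; the normalization cancels in
`Peak_A/Peak_GR`). Donor/SV/breakpoint counts are taken over the region.

The recurrence-score null is a two-parameter Gamma (location 0) fitted by
maximum likelihood to the cohort's PRs values; p-values are upper-tail
probabilities, corrected by Benjamini–Hochberg at FDR < 0.2. The
square-root transform of PRs is retained as the dispersion-reduced display
scale (QQ data), but the null is fitted to PRs itself: on driver-free
synthetic cohorts the Gamma probability-integral transform of raw PRs is
uniform (KS p ≥ 0.05 across 20 seeds) while the sqrt-scale fit shows
systematic light tails. The SSRs null uses the same Gamma+BH machinery;
peaks with ≤ 2 donors are flagged regardless. Cohorts with fewer than 10
peaks skip significance with a warning. Degenerate zero-area peaks (a
single support point with no interpolable flanks) receive p = 1.

Element scoring treats a CDS record as one gene-level interval: both
`ERS_SV` (SVs in the peak whose extent touches the element; a
translocation counts through either breakend since it has no contiguous
span) and `ERS_BP` (peak breakpoints inside the element) use that span.
Ties in `best_score` break by higher donor count, then shorter element,
then element id; across classes, an optional known-cancer-gene list
(directly or through an enhancer→gene link) resolves top-score ties.

## Detection power

`p0 = 1 − (1 − μ·f_p)^L` and `p1 = 1 − (1 − p0)(1 − r·s)` with power
`P(Bin(n, p1) ≥ m_min)`. The donor threshold `m_min` (default 3) is
exposed because no canonical value exists. Two variants are provided: the
fixed-threshold tail (the closed-form used in the worked checks) and a
background-calibrated threshold — the smallest donor count exceeded by
chance with probability ≤ 0.05 under `Bin(n, p0)`, floored at `m_min` —
used for the cohort-size-versus-peak-length curves, where it produces the
expected behavior that narrow peaks need fewer donors. When not supplied,
`μ` is the mean SV count per donor over the genome length and `f_p` the
breakpoint-density ratio of the top-2% peaks to the genome.

## Synthetic cohorts

Defaults: twenty 25-Mb chromosomes, 200 donors, 25 background SVs per
donor, five 100-kb driver loci at 25% prevalence with 5-kb breakend
jitter, DEL-dominant type mix with 10% translocations, a 37-sample TAD
panel. The layout was chosen so that (a) each chromosome carries a few
hundred breakpoints — an injected cluster (~100 breakends) is then
comparable to the span-0.2 LOESS window, the regime in which proximity
peak calling resolves hotspots; and (b) injected breakpoints stay a small
minority (~4%) of all rows, as driver loci are in real cohorts, so the
background fit is not dominated by them. Covariate tracks are generated
with realistic autocorrelation (sticky Markov chains for factor tracks,
smoothed random walks for RT, AR(1) for GC); background breakend intensity
is log-linear in the covariates with per-bin multiplicative Gamma noise
(an identity-link generation mode exists for exact-recovery experiments).
TAD panels perturb a master partition by boundary drops, 50-kb jitter and
per-domain disruptions whose rates are Beta-distributed, giving recurrence
values spread over (0, 1]. Background annotation elements never intersect
a driver locus, so recovery benchmarks have an unambiguous planted truth —
two co-deleted elements are indistinguishable to a rearrangement score.

What the simulator does **not** emulate: chromothripsis/chromoplexy and
other clustered multi-SV processes (every background SV is independent, so
`Nsmp ≈ Nsv` in background peaks), copy-number structure, sequencing or
calling artifacts, mappability gaps and real chromosome-scale covariate
structure. Passing tests therefore demonstrate the statistical machinery
under the stated generative assumptions, not performance on real cohorts.

## Numerical conventions

Internal coordinates are 0-based half-open; the 12-column SV table is read
as 1-based inclusive and converted once on input. The breakend *start*
column is the breakpoint position (consensus calls carry confidence
intervals; a single deterministic point is required). Breakpoints sort by
(position, donor, SV id) for a stable tie order. All pipeline randomness
(k-means seeding included) derives from one seed recorded in the run
manifest; staged CLI runs serialize intermediates at full float precision
so staged and monolithic execution are byte-identical.

## Limitations

* Explained deviance on synthetic cohorts (~10–25%) reflects the
  generator's modest covariate effect sizes; it is not evidence about any
  real cohort.
* The blocked-CV smoothing selection needs at least two modeled
  chromosomes; single-chromosome inputs fall back to GCV, which can
  undersmooth a serially correlated curve.
* Valleys (candidate negative selection) are not analyzed.
* Expression-based validation of candidates and external database lookups
  are out of scope; the known-gene list is user-supplied.
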