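# Methods

This note documents the statistical procedures implemented in `metabopls`,
the defaults and the reasoning behind the genuinely open design choices,
and what the synthetic-data experiments do and do not demonstrate.

## Data model

A `MetaboliteTable` is an n×p matrix of metabolite concentrations (signal
integrals), one binary group label per sample, and a biofluid block tag per
variable.  Variables are named `<block>__<metabolite>` so names stay unique
after fusion.  Fusion is *low-level*: blocks are concatenated column-wise
(rows aligned by sample id; every sample must appear in every block, as in
a design that keeps only patients with all biofluids collected) and the
fused matrix is autoscaled as one, so each variable contributes equally
regardless of block or unit.

Autoscaling (per-variable mean 0, SD 1; SD with divisor n−1) is always
*fitted on the model set* and applied to test and bootstrap out-of-bag
samples.  The source study does not state where scaling was estimated;
fitting it on the model set is the leakage-safe choice and is refit inside
every cross-validation fold and every bootstrap replicate (a flag allows
fixed scaling).  A column whose SD is below 1e-12 of its magnitude raises a
zero-variance error naming the variable; deep inside resampling loops,
where a degenerate resampled column must not abort a thousand-replicate
run, the SD silently falls back to 1 (the column is centered and carries no
signal either way).

## Normalization and binning

PQN follows the standard dilution-correction recipe: every spectrum is
first scaled to the median total integral of the set, the reference is the
pointwise median (optionally mean) of the integral-normalized spectra, and
each spectrum is divided by the median of its pointwise quotients against
the reference over the reference's positive support.  The returned factor
is the product of the two scalings, so `output = input / factor`.  The
method only names PQN in the motivating study; the Dieterle-style dialect
(initial integral normalization + median reference) is our choice and is
validated by exact recovery of simulated dilution factors up to one global
constant.

Equal-width binning anchors bin edges at the maximum ppm of the axis and
proceeds downward; the value of a bin is the *sum* of the intensities of
the points falling in it, the last partial bin is kept (bin count
⌈range/width⌉), and the total integral is conserved exactly.  Points
sitting numerically on a bin edge are nudged by 1e-9 bin widths so float
error cannot move them across the edge.  The printed bin counts of the
motivating study imply integration ranges it never states, so bin counts
are not used as checks.

## Kennard–Stone balanced splitting

The model/test split must be deterministic, representative and balanced.
Kennard–Stone is applied separately to each group on that group's
autoscaled data (Euclidean distance): the first two picks are the mutually
most distant pair, each further pick maximizes the minimum distance to the
already-selected set.  Per group, k = ⌊fraction × smaller group size⌋
samples enter the model set (fraction 0.75; 18/28 → 13+13 model, 5+15
test).  Floor is used because 0.75 × 18 = 13.5 must yield the reported 13.
All distance ties break to the lowest row index — the module contains no
randomness.  Whether scaling for the distance was per group or global is
ambiguous in the source; per-group is the default, global is a flag.  A
seeded uniform splitter exists solely as the baseline in a
representativity property test.

## PLS-DA core

With a single ±1 response, the NIPALS weight update is closed-form per
component: w ∝ Xᵈᵀy, t = Xᵈw, p = Xᵈᵀt/tᵀt, q = yᵀt/tᵀt, followed by
X-deflation (y-deflation is algebraically redundant in the one-response
case).  The regression vector b = W(PᵀW)⁻¹q collapses the model into one
linear predictor; PᵀW is unit upper triangular, so the cumulative b for
every complexity comes from back substitution.  Class assignment
thresholds ŷ = x·b at 0 — the natural cut-off when the model set is
balanced, which is precisely why the split is balanced — and a score of
exactly 0 goes to the negative-coded class.  The positive class defaults
to the larger cohort (OSAS in the motivating design) so sensitivity refers
to it.

Complexity is selected by leave-one-out cross-validation minimizing the
misclassification count, ties to the smaller model (the source states LOO
but not the loss; misclassification matches the discriminant use, and
parsimony is the conventional tie-break).  The LOO implementation derives
each fold's scaled cross-product matrices by rank-one downdates of the
full-data Gram matrix and extracts components with the non-deflating
r-vector kernel recursion, batched over all folds; this is algebraically
identical to refitting NIPALS on every explicit fold matrix (a property
test asserts the equality) and is what makes complexity re-selection
inside every bootstrap replicate affordable (A_max capped at 5).

**VIP.**  VIPⱼ = √(p Σₐ SSYₐ wⱼₐ²/Σₐ SSYₐ) with SSYₐ = qₐ²tₐᵀtₐ the
response variance captured by component a.  Mean squared VIP is exactly 1
for any fitted model, which anchors cut-offs near 1; the workflow default
is 0.8.

**Target projection and SR.**  The A-component model is collapsed onto its
predictive direction w_TP = b/‖b‖; the target score t_TP is computed on
the reconstruction TPᵀ by default (raw-X variant by flag).  The TP loading
p_TP = Xᵀt_TP/t_TPᵀt_TP is the least-squares slope of each variable on the
target score (identical whether taken against X or the reconstruction,
because the discarded residue is orthogonal to the score space).  The
selectivity ratio is SRⱼ = explainedⱼ/residualⱼ with
explainedⱼ = t_TPᵀt_TP · p_TPⱼ² the regression SS of variable j on the
target component and residualⱼ = totalⱼ − explainedⱼ its lack of fit
against the *measured* variable.  Booking the residual against the
measured matrix rather than the reconstruction is deliberate: with
reconstruction-based totals, a variable nearly absent from the model span
has a near-zero denominator and a wildly inflated SR, which empirically
destroys the SR ranking on synthetic data; the data-based definition is
also what an independent per-variable regression on t_TP yields, which is
how the tests validate it.  A variable whose residual falls below 1e-12 of
its total is reported as +inf and always retained.

## Bootstrap engine and selection

Each replicate resamples the model set with replacement *within each
group* (stratified — a replicate can therefore never lose a class),
refits scaling, re-selects complexity by LOO, fits, and records the AUC on
the replicate's out-of-bag model-set samples together with VIP and/or SR
profiles.  A replicate whose out-of-bag set misses a group is redrawn (and
logged); with 13+ samples per group this has probability ~2×10⁻⁵.
Out-of-bag AUC is the default figure of merit because in-bag AUC of a
refitted model is structurally optimistic (a flag provides it for
comparison); whether the motivating study scored in- or out-of-bag is not
stated.  Aggregates are the mean AUC θ̄*, the standard error
se_b = √(Σ(θᵢ*−θ̄*)²/(b−1)) (the divisor-(b−1) sample SD — asserted
against that oracle), the mean per-variable VIP/SR (an infinite SR in any
replicate propagates to an infinite average), and the per-replicate chosen
complexities.

*VIP selection* drops variables with average VIP < cut-off (default 0.8)
and repeats the whole bootstrap on the survivors, three rounds by default,
stopping early when nothing is dropped or fewer than two variables remain;
an audit trail records the drops per round.  A cut-off of 0 is the
identity selection.  *SR selection* is a single pass retaining variables
with average SR ≥ cut-off.

**DIVA/MCCR cut-off.**  The cited discriminating-variable test is not
restated in the motivating study, so the protocol here is explicit, seeded
and configurable: variables are sorted by average SR and partitioned into
`intervals` (default 10) near-equal-count groups; each variable's
discrimination is scored as the mean held-out accuracy of an
optimal-threshold univariate classifier over `reps` (default 100)
stratified half/half resampled evaluations; an interval's MCCR is the mean
over its members.  The cut-off is the lower SR edge of the first interval
(increasing SR) whose MCCR exceeds the threshold (default 60 %, the
magnitude of the MCCRs printed in the motivating study); if none exceeds
it the best interval's lower edge is used.  Quantile (equal-count) rather
than equal-width intervals keep every interval populated in the heavily
right-skewed SR distributions these models produce.

## Evaluation

AUC is the Mann–Whitney probability that a positive score outranks a
negative one, ties ½, computed from tie-averaged ranks (the loop-free form
matters: the bootstrap evaluates it thousands of times per run); tests
assert equality with exhaustive pair counting and with an independent
library implementation.  Sensitivity, specificity and efficiency (the
non-error rate) are the usual percentages with the positive class the
larger cohort by default.  Panel overlap is reported as a count and as
round(100·common/total block variables), matching the arithmetic of the
published COPD/OSAS panels (7/16 → 44 %, 12/31 → 39 %).  The published
urine row reports an overlap count inconsistent with its own printed
lists; it is transcribed as printed and never asserted.

## Synthetic cohorts

The generator emulates the motivating study design, not NMR physics.
Log-concentrations are Gaussian: zᵢⱼ = μⱼ + σ(√ρ gᵢ + √(1−ρ) εᵢⱼ) + δⱼσ
for group-B samples, with per-variable baselines μⱼ ~ U(ln 0.1, ln 10)
(metabolite abundances span orders of magnitude), a shared latent factor g
per sample and block inducing within-block equicorrelation ρ (default 0.3
— the study reports no correlation estimates, so this is a stated
assumption of moderate within-fluid dependence, not a fact), log-scale SD
σ = 0.5 (typical biological CV of ~50 %), and planted effects δⱼ in
pooled-SD units on the log scale.  Concentrations are exp(z): positive and
right-skewed, as NMR integrals are.  Across-block correlation defaults to
0.  Default dimensions mirror the study (18/28; EBC 16, serum 31, urine
27) so pipeline-shape tests run on defaults.  Spectrum fixtures are a
common sum-of-Gaussians template times a per-sample dilution factor
(optionally with multiplicative point noise); they exercise PQN and
binning, nothing more — no multiplets, no peak shifts, no baseline.

Because the clinical NMR data behind the motivating study are not
deposited, its headline real-data AUC/sensitivity/specificity tables are
not reproducible here.  What the simulation experiments show is that the
*machinery* behaves as claimed: the split arithmetic, the analytic
identities, chance-level behavior under label permutation (mean bootstrap
AUC within 0.5 ± 0.1), and recovery of all five planted 1.5-SD biomarkers
by both selection procedures in ≥ 90 of 100 seeded 60/60 cohorts (B = 100
per bootstrap pass in that experiment; the pipeline default remains
B = 1000).  They do not show that the procedures would select the same
metabolites on real patients, where effect sizes, correlation structure
and non-normality are unknown.

## Numerical choices and limitations

* Seeds: every stochastic routine takes an explicit seed; VIP rounds
  derive per-round seeds from one generator, so a full run is reproducible
  bit for bit.
* Degenerate inputs: single-class labels, excess complexity (beyond
  min(n, p) or the predictive rank), all-zero spectra, zero-variance
  columns at fit time, and empty selections all raise errors with
  actionable messages.
* The small-sample Kennard–Stone test set is *not* random: test-set
  figures of merit are conditional on the deterministic split, as in the
  motivating design, and carry no sampling-distribution interpretation.
* No OPLS (the predictive component is obtained by target projection
  instead), no percentile/BCa bootstrap intervals (mean ± se only), no
  spectral alignment or baseline correction, and no parallel execution —
  replicates are sequential but cheap (a B = 1000 bootstrap of the default
  26-sample model set takes a few seconds).
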