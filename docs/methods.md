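# Methods

`stagedisc` asks a simple question of a labeled multivariate BOLD time
series: do the voxel activity patterns of a region differ between temporally
adjacent stages of a cognitive task, and which voxels carry that
information?  This note documents the statistical machinery, the synthetic
data model used to validate it, and the numerical and design choices made
where more than one convention exists.

## Data model

The unit of analysis is a scans × voxels matrix for one region of interest
(ROI), sampled at a repetition time TR (2 s by default), together with a
per-scan stage label in {0..K} (0 = unlabeled) and a trial id.  The
canonical design has K = 6 stages per trial — four successive evidence draws,
a behavioral response, and a confidence rating — repeated over 8 trials with
unlabeled inter-trial gaps.

### Preprocessing

Per voxel, in this order: linear detrend; removal of slow scanner drift by
regression on a discrete-cosine basis containing every component with period
longer than the high-pass cutoff (256 s by default, the SPM convention);
z-scoring.  The ordering guarantees the advertised unit-variance property of
the output.  A voxel with zero residual variance after filtering cannot be
standardized and is dropped with a logged warning rather than zero-filled.
The first k volumes of a run (magnetic saturation) are discarded jointly
from data and labels before anything else.

### Hemodynamic alignment

BOLD responses lag their neural causes by seconds, so stage labels must be
shifted forward before any stage statistic is computed.  The lag is
estimated by scanning candidate shifts 0..max_lag (default 5 TRs): at each
shift, the voxel matrix (reduced to principal components explaining 95% of
variance, capped at one tenth of the labeled scan count) is canonically
correlated with the K−1 stage indicator columns, and the lag maximizing the
canonical association `1 − Π(1 − ρ_i²)` is returned.

Two estimator-design facts found during development are worth recording:

* The **first** canonical correlation is useless as a lag profile: because
  the hemodynamic response smears each stage's pattern into its neighbors, a
  single near-perfect canonical direction exists at *every* candidate shift
  (saturation ≈ 0.95 even in the noiseless limit).  Pooling the whole
  canonical spectrum restores contrast between shifts.  The first-canonical
  profile is still recorded on the result object for reference.
* With all stage epochs of identical length, the lag is only identifiable
  **up to one epoch**: shifting labels by a whole epoch relabels stages
  consistently, producing an equally discriminable configuration (failures
  land at lag ± one epoch, never adjacent lags).  Designs with heterogeneous
  epoch durations do not alias; the lag-recovery benchmark therefore uses
  2-TR evidence epochs with 3-TR response/rating epochs.

## Stage discriminability statistics

Labeled scans are decomposed into the between-stage scatter
`H = Σ_k n_k (μ_k − μ)(μ_k − μ)ᵀ` and the within-stage scatter
`E = Σ_k Σ_{i∈k} (x_i − μ_k)(x_i − μ_k)ᵀ` (H + E equals the total scatter, an
identity asserted in the tests).  The eigenvalues λ_i of `H E⁻¹` — computed
through a Cholesky whitening of E for numerical stability, with optional
shrinkage of E toward its diagonal when singular — yield the three classical
multivariate statistics:

* Wilks' Λ = Π 1/(1+λ_i)      (1 = no separation)
* Lawley–Hotelling trace = Σ λ_i   (the "generalized T²"; 0 = no separation)
* Roy's greatest root = max λ_i

Conventions: the generalized T² is implemented as the Lawley–Hotelling trace
tr(HE⁻¹) without degrees-of-freedom factors, and Roy's statistic as the raw
largest eigenvalue λ₁ rather than θ = λ₁/(1+λ₁).  Both choices are
immaterial downstream because every statistic is normalized by its own
permutation null, which cancels multiplicative conventions; they are
declared here because cross-package numerical equality is not otherwise
guaranteed.

Pairwise stage differences are squared Mahalanobis distances between stage
means under the shrinkage-regularized pooled covariance
`Σ̂ = (1−λ)Σ + λ diag(Σ)` (pooled divisor n − K; default λ = 0.1, always
configurable and recorded in outputs).  Distances are computed via
triangular solves, never an explicit inverse.  At λ = 0 they are invariant
under invertible linear transforms of the data (tested property).

For the 6-stage design two phase scores summarize the distance matrix: the
*decision-making* contrast (mean distance of evidence stages 1–3 to the
final evidence stage 4) and the *decision-evaluation* contrast (mean
distance of stages 1–3 to the response/rating stages 5–6).

## Block-permutation bootstrap

Scan-wise permutation would destroy the autocorrelation that makes fMRI
stage comparisons anti-conservative, so the null is built by permuting, within
each trial, the order of maximal runs of identical consecutive labels
(unlabeled runs participate, keeping the run-length composition intact).
This preserves per-trial label counts, run lengths, and within-run
autocorrelation exactly; the conservation is asserted on every draw in the
test suite.

To compare ROIs of different sizes, a statistic is always the average over
`n_draws` (default 50) random voxel subsets of fixed size v (by convention
the size of the smallest ROI under joint analysis).  Significance comes from
`n_bootstrap` (default 1000) such values on independently permuted labels:
the add-one p-value `(1 + #{null ≥ observed})/(1 + B)`, the ratio
observed/null-mean ("fold above null" — chosen because a no-signal region
then sits interpretably near 1), and a z-score are all reported.

Distance matrices are normalized pair by pair against each pair's own
permutation distribution.  One honest caveat, measured on null simulations:
block permutation randomizes the temporal spacing *between* runs, so for
autocorrelated noise the observed distance of temporally adjacent stage
pairs sits conservatively below its permutation mean (≈0.77 at AR(1) 0.4)
while distant pairs sit slightly above (≈1.17).  Under exchangeable noise
every pair normalizes to 1 within tolerance.  Inference on individual near
pairs is therefore conservative, which is the safe direction.

Seeding: one master seed; per-bootstrap and per-draw substreams are spawned
deterministically (`numpy.random.SeedSequence`), so results are identical
for a given seed regardless of execution order.

## Voxel selection by penalized cross-validation

The classifier is a minimum-Mahalanobis regularized LDA: a scan's pattern
over the voxel set S is assigned to the stage k minimizing
`δ_k(x) = (x − μ_k) Σ̂⁻¹ (x − μ_k)ᵀ`; ties break toward the earliest class.
The quality of S is the leave-one-out cross-validation error CVE(S) — the
fraction of scans misclassified by a model fit without them.  The printed
definition of CVE in the source literature uses an indicator of *correct*
classification inside the average, which would make it an accuracy; it is
implemented as the misclassification fraction, since it is explicitly an
"error" that the search minimizes.

Leave-one-out is computed exactly by rank-one downdates of the class means
and within-class scatter, batched over scans with stacked linear algebra —
algebraically identical to refitting per left-out scan.  A naive
refit-from-scratch oracle is kept in the test suite and agreement is exact
on every tested instance.

Set size is penalized through `PCV(S) = CVE(S) × (1 + ξ·|S|/log n)` (natural
log; n = labeled scans).  The search adds the candidate voxel minimizing the
CVE (ties toward the lowest voxel index) while the PCV strictly decreases,
starting from the empty-set baseline `PCV(∅) = 1 − max_k n_k/n` (the error
of majority guessing); it then deletes voxels, ranked by the PCV their
removal would produce, while the PCV is non-increasing.  Both stopping rules
and the tie-breaks are deterministic; every recorded (CVE, |S|) pair on the
trace satisfies the PCV formula bit-exactly.

Two penalty constants appear in the source literature (ξ = 0.1 in the
methods, ξ = 1 in the figure demonstrating the error curve).  The library
default is ξ = 0.1; the planted-recovery benchmark uses ξ = 1 because the
weaker penalty decays as 1/log n while the per-step selection bias of the
greedy LOO search decays only as n^(−1/2), so at benchmark sizes a ξ = 0.1
search keeps absorbing noise voxels (measured: 4–11 selected on pure noise,
with CVE ≈ 0.2 below chance) whereas ξ = 1 selects nothing on noise and
recovers planted voxels essentially perfectly.

Selected voxels are attributed to their ROIs; each ROI's share of the
selection (posterior) is divided by its share of the candidate mask (prior)
to give a lift that corrects for unequal mask sizes, and the per-subject
consistency of lift orderings is assessed with an exact two-sided binomial
sign test at rate ½.

## Synthetic data generator

The generator emulates a blocked multi-stage acquisition with planted ground
truth: stage box-cars convolved with a double-gamma hemodynamic response,
weighted by per-stage spatial patterns on a chosen subset of "informative"
voxels, plus AR(1) Gaussian noise (independent across voxels; optionally one
shared global component), then per-voxel standardization.  The same seed
reproduces a dataset bit for bit, and the informative voxel ids, stage
patterns and planted lag are recorded.

Choices that matter:

* **HRF**: double gamma with peak-shape 5.4 (continuous peak at 4.4 s,
  undershoot near 15 s).  A conventional 6.0 shape peaks at 5.0 s, but its
  2 s-sampled argmax falls at 3 TRs; the 5.4 shape keeps the sampled peak —
  and hence the planted, recoverable lag — at 2 TRs, matching the empirical
  hemodynamic delay the toolkit is designed around.  The kernel sampled at
  the TR is normalized to unit peak so `effect_amplitude` is expressed in
  units of the marginal noise SD.
* **Noise**: AR(1) with lag-1 coefficient 0.4 and unit marginal SD —
  mid-range for BOLD at TR = 2 s, and strong enough that the block bootstrap
  is non-trivially necessary.
* **Stage patterns**: per-stage weights over the informative voxels, drawn
  once per dataset.  Three bases: iid Gaussian (default), random-sign unit
  magnitude (equal per-voxel effect size), and deterministic Helmert
  contrasts (voxel j separates stage j+1 from stages 1..j, so the full
  voxel set is needed for complete stage discrimination).  Gaussian weights
  are the realistic default but make "recover the planted voxels" ill-posed
  as a benchmark — a voxel with a near-zero weight is unrecoverable in
  principle, and at strong per-voxel separations a CVE-minimizing search
  correctly stops after 2–3 voxels because the rest are redundant.  The
  recovery benchmark therefore plants the Helmert code.
* **Benchmark conditions** (fixed in `synthgen.lag_benchmark`,
  `null_benchmark`, `selection_benchmark`, `crossover_benchmark`): the lag
  benchmark uses a strongly activated ROI (40 voxels, 20 informative,
  orthogonalized patterns, amplitude 2 SD) with heterogeneous epochs, see
  above; the selection benchmark plants 5 Helmert-coded voxels among 100
  with the amplitude calibrated by bisection so the mean per-voxel
  stage-1-vs-4 separation is 1.5 pooled-SD units; the crossover benchmark
  plants a decision-stage ROI (36 voxels) against a response/rating ROI
  (29 voxels, unequal like real anatomical masks) at amplitude 1.2 with
  4-TR epochs — with shorter epochs the decision region's hemodynamic tail
  extends so far into the response stage that it legitimately discriminates
  the evaluation contrast, blurring the planted dissociation.

What the generator does **not** emulate: spatial smoothness and anatomy,
physiological (cardiac/respiratory) noise, motion, scanner drift beyond the
deterministic trend the preprocessing removes, and behavioral variability in
stage durations.  Passing the synthetic benchmarks therefore demonstrates
the correctness and calibration of the statistical machinery under the
stated noise model, not performance on any particular acquired dataset.

## Problem sizes

The shipped benchmarks are sized for a single CPU: 8-trial designs with
136–232 scans, ROIs of 8–100 voxels, 50–200 permutations per null, 50–500
replicate datasets per property.  These sizes were chosen so each
distributional claim is tested with a meaningful binomial margin.

## Known limitations

* The forward search evaluates every candidate voxel per step; cost grows
  linearly in ROI size and quadratically in selected-set size.  Whole-brain
  searchlights are out of scope.
* Pair-specific permutation nulls are conservative for temporally adjacent
  stage pairs under autocorrelated noise (see above).
* Group-level aggregation exports per-subject tables with mean/SEM rows;
  inferential across-subject models (repeated-measures ANOVA etc.) are left
  to standard statistics packages operating on those tables.
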