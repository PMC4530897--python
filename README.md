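# stagedisc

Multivariate discrimination of temporally adjacent cognitive task stages in
fMRI BOLD time series.

Most fMRI decoding studies discriminate conditions that are well separated
in time.  `stagedisc` targets the harder setting where the classes are
*successive stages of a single continuously evolving task* — e.g. four
evidence draws, a behavioral response, and a confidence rating within one
trial — so that temporal autocorrelation, hemodynamic lag, and unequal ROI
sizes all conspire against naive statistics.  It is a library and CLI for
researchers who want to ask, per region of interest: *how much information
about task stage does this region's voxel pattern carry, between which
stages, and through which voxels?*

## What it computes

Given a scans × voxels matrix per ROI and per-scan stage labels 1..K
(0 = unlabeled):

* **Stage discriminability.**  From the between/within scatter decomposition
  `H + E = T` over labeled scans, the three classical MANOVA statistics on
  the eigenvalues λᵢ of `HE⁻¹`: Wilks' Λ = Π 1/(1+λᵢ), the Lawley–Hotelling
  trace (generalized T²) = Σ λᵢ, and Roy's greatest root = λ₁.
* **Pairwise stage distances.**  Squared Mahalanobis distances between stage
  means under the shrinkage-regularized pooled covariance
  Σ̂ = (1−λ)Σ + λ·diag(Σ), collapsed for 6-stage designs into
  *decision-making* (stages 1–3 vs 4) and *decision-evaluation*
  (stages 1–3 vs 5–6) phase contrasts.
* **Honest significance under autocorrelation.**  A block-permutation
  bootstrap that shuffles whole runs of identical labels within each trial,
  preserving run lengths and within-run autocorrelation; statistics are
  averaged over random fixed-size voxel subsets to make ROIs of different
  sizes comparable, and reported as fold-above-null with exact add-one
  permutation p-values.
* **Hemodynamic alignment.**  The label shift (in TRs) maximizing the
  canonical association between the voxel time series and stage indicators.
* **Maximally predictive voxel sets.**  A forward-addition/backward-deletion
  search over voxels driven by the leave-one-out error of a
  minimum-Mahalanobis regularized LDA classifier, stopped by the penalized
  criterion `PCV = CVE × (1 + ξp/log n)`; selected voxels are attributed to
  ROIs as posterior/prior lifts and compared across subjects with exact
  sign tests.
* **Synthetic ground truth.**  A seeded generator of labeled BOLD-like data
  (double-gamma HRF, AR(1) noise, planted stage patterns) so every claim
  above is testable without any acquired data.

## Worked example

Two planted regions: a *decision* ROI whose pattern appears only in the
final evidence stage, and an *evaluation* ROI with response/rating patterns.

```python
import stagedisc as sd
from stagedisc import permboot, pcvselect
from stagedisc.cli import _concat_rois

design, rois = sd.synthgen.crossover_benchmark()
ds = sd.simulate_dataset(design, rois, seed=42)

lag = sd.estimate_lag(ds.rois["decision"], ds.labels, max_lag_trs=5)
labels = sd.shift_labels(ds.labels, lag.lag_trs)

cfg = permboot.BootstrapConfig(n_bootstrap=500, n_draws=1, seed=0)
for name in ("decision", "evaluation"):
    nb = permboot.bootstrap_null(ds.rois[name], labels,
                                 permboot.stat_lawley_hotelling, cfg, 7)
    print(f"{name:10s} T2 = {nb.observed:.3f}  "
          f"fold above null = {nb.normalized:.2f}  p = {nb.p:.4f}")

nd = permboot.normalized_distance_matrix(
    ds.rois["decision"], labels,
    cfg=permboot.BootstrapConfig(n_bootstrap=200, n_draws=1, seed=1))
making, evaluation = sd.phase_contrast(nd.normalized)
print(f"decision ROI: making = {making:.2f}, evaluation = {evaluation:.2f}")

combined = _concat_rois(dict(ds.rois))
trace = pcvselect.forward_backward_select(
    combined, pcvselect.phase_labels(labels, "making"))
attr = pcvselect.roi_attribution(
    trace,
    {str(v): n for n, ts in ds.rois.items() for v in ts.voxel_ids},
    {n: ts.n_voxels for n, ts in ds.rois.items()})
print(f"selected {len(trace.final_set)} voxels, CVE = {trace.final_cve:.3f}")
print("lifts:", {k: round(v, 2) for k, v in attr.lifts.items()})
```

prints

```
estimated hemodynamic lag: 2 TRs
decision   T2 = 5.691  fold above null = 2.42  p = 0.0020
evaluation T2 = 10.042  fold above null = 5.45  p = 0.0020
decision ROI: making = 5.89, evaluation = 1.27
selected 3 voxels, CVE = 0.016
lifts: {'decision': 1.81, 'evaluation': 0.0}
```

Reading it: the estimator recovers the planted 2-TR hemodynamic lag; both
regions carry significant stage information relative to their own
block-permutation nulls (fold above null ≫ 1, p = 2/(B+1) — the smallest
value B = 500 permutations can produce); within the decision ROI the
normalized Mahalanobis contrast peaks at the decision point
(making 5.89 ≫ evaluation 1.27); and on the decision-making contrast the
voxel search selects a 3-voxel set classifying at CVE 1.6% whose members
come disproportionately from the decision mask (lift 1.81 vs 0).

The same pipeline runs from the shell:

```sh
stagedisc simulate --seed 42 --out data/
stagedisc select --rois data/decision.nii,data/evaluation.nii \
    --labels data/labels.tsv --contrast making --out out/
stagedisc run --config examples/config.yaml --out results/   # full pipeline
```

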