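"""Synthetic labeled BOLD generator with planted ground truth.

Emulates a blocked cognitive-task acquisition: trials of K consecutive stages
(evidence draws, behavioral response, choice rating) separated by unlabeled
gaps, sampled at a fixed TR.  Stage-specific spatial patterns are planted on a
subset of "informative" voxels, convolved with a canonical double-gamma
hemodynamic response so the signal arrives with a realistic lag, and buried in
AR(1) Gaussian noise.  Ground truth (informative voxel ids, planted lag,
per-stage patterns) is recorded so recovery can be scored.

Defaults mirror the study design this toolkit targets: 8 trials, 6 stages,
TR = 2 s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .prep import StageLabelSeries, VoxelTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "TaskDesign",
    "RoiSpec",
    "GroundTruth",
    "SyntheticDataset",
    "make_design",
    "canonical_hrf",
    "simulate_dataset",
    "measured_separation",
    "calibrate_amplitude",
    "write_dataset",
]

DEFAULT_TR_SECONDS = 2.0
DEFAULT_N_TRIALS = 8
DEFAULT_N_STAGES = 6
# Stage epoch length in TRs; configurable, chosen consistent with ~2-minute
# trials sampled at TR = 2 s.
DEFAULT_STAGE_DURATION_TRS = 2
DEFAULT_GAP_TRS = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskDesign:
    """Blocked task structure: ``n_trials`` trials, each one maximal run per
    stage in canonical order 1..K, followed by an unlabeled inter-trial gap."""

    n_trials: int
    stage_durations: tuple[int, ...]
    inter_trial_gap: int
    tr_seconds: float = DEFAULT_TR_SECONDS

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.stage_durations:
            raise ValueError("stage_durations must be non-empty")
        if any(d < 1 for d in self.stage_durations):
            raise ValueError("every stage duration must be >= 1 TR")
        if self.inter_trial_gap < 0:
            raise ValueError("inter_trial_gap must be >= 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "stage_durations", tuple(int(d) for d in self.stage_durations))

    @property
    def n_stages(self) -> int:
        return len(self.stage_durations)

    @property
    def n_scans(self) -> int:
        return self.n_trials * (sum(self.stage_durations) + self.inter_trial_gap)


def default_design(
    n_trials: int = DEFAULT_N_TRIALS,
    n_stages: int = DEFAULT_N_STAGES,
    stage_duration: int = DEFAULT_STAGE_DURATION_TRS,
    gap: int = DEFAULT_GAP_TRS,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> TaskDesign:
    """The canonical simulation design: 8 trials x 6 stages of 2 TRs at TR=2 s."""
    return TaskDesign(
        n_trials=n_trials,
        stage_durations=(stage_duration,) * n_stages,
        inter_trial_gap=gap,
        tr_seconds=tr_seconds,
    )


@dataclass(frozen=True)
class RoiSpec:
    """Configuration of one simulated ROI.

    ``stage_pattern_mode`` controls which stages carry a distinct spatial
    pattern on the informative voxels: the string ``"all"`` (every stage) or an
    explicit collection of stage numbers (e.g. ``(4,)`` for a region only
    informative about the decision stage, ``(5, 6)`` for an
    evaluation-sensitive region).  Stages outside the set contribute no
    stage-specific signal.

    ``ar_coefficient`` is the lag-1 autocorrelation of the per-voxel noise;
    ``noise_sd`` is the marginal (stationary) noise standard deviation.
    ``effect_amplitude = 0`` yields a pure-noise control ROI.
    """

    name: str
    n_voxels: int
    n_informative: int = 0
    effect_amplitude: float = 0.0
    stage_pattern_mode: str | tuple[int, ...] = "all"
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0
    orthogonal_patterns: bool = False
    # "gaussian": iid N(0,1) weights; "unit": random-sign equal magnitude;
    # "helmert": orthogonal stage contrasts spread over voxels, so every
    # informative voxel separates a distinct subset of stages and the full
    # set is needed for complete stage discrimination
    pattern_strength: str = "gaussian"

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not (0 <= self.n_informative <= self.n_voxels):
            raise ValueError("n_informative must lie in [0, n_voxels]")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.pattern_strength not in ("gaussian", "unit", "helmert"):
            raise ValueError("pattern_strength must be 'gaussian', 'unit' or 'helmert'")
        if not isinstance(self.stage_pattern_mode, str):
            object.__setattr__(
                self, "stage_pattern_mode", tuple(int(s) for s in self.stage_pattern_mode)
            )

    def pattern_stages(self, n_stages: int) -> tuple[int, ...]:
        if self.stage_pattern_mode == "all":
            return tuple(range(1, n_stages + 1))
        if isinstance(self.stage_pattern_mode, str):
            raise ValueError(f"unknown stage_pattern_mode {self.stage_pattern_mode!r}")
        bad = [s for s in self.stage_pattern_mode if not 1 <= s <= n_stages]
        if bad:
            raise ValueError(f"stage_pattern_mode stages out of range: {bad}")
        return self.stage_pattern_mode


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one simulated dataset."""

    informative_voxels: Mapping[str, np.ndarray]
    lag_trs: int
    stage_patterns: Mapping[str, np.ndarray]  # per ROI: (K, n_informative)


@dataclass(frozen=True)
class SyntheticDataset:
    rois: Mapping[str, VoxelTimeSeries]
    labels: StageLabelSeries
    ground_truth: GroundTruth
    seed: int


# ---------------------------------------------------------------------------
# Design / HRF
# ---------------------------------------------------------------------------


def make_design(
    n_trials: int,
    stage_durations: Sequence[int],
    inter_trial_gap: int,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> StageLabelSeries:
    """Build the per-scan stage-label and trial-id series for a blocked design.

    Each trial is the concatenation of one run per stage (labels 1..K in
    order) followed by ``inter_trial_gap`` unlabeled scans (label 0).
    """
    design = TaskDesign(
        n_trials=n_trials,
        stage_durations=tuple(stage_durations),
        inter_trial_gap=inter_trial_gap,
        tr_seconds=tr_seconds,
    )
    trial_labels = np.concatenate(
        [
            np.repeat(k + 1, d)
            for k, d in enumerate(design.stage_durations)
        ]
        + [np.zeros(design.inter_trial_gap, dtype=int)]
    ).astype(int)
    labels = np.tile(trial_labels, design.n_trials)
    trial_ids = np.repeat(np.arange(design.n_trials), trial_labels.size)
    return StageLabelSeries(labels=labels, trial_ids=trial_ids, n_stages=design.n_stages)


def canonical_hrf(
    t: float | np.ndarray,
    peak_delay: float = 5.4,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response.

    ``h(t) = g(t; peak_delay, peak_disp) - ratio * g(t; undershoot_delay,
    undershoot_disp)`` with gamma-density components; peaks near 4.4 s and
    dips (undershoot) near 15 s with the defaults, so a series sampled at
    TR = 2 s carries its stage information with a 2-TR lag.  ``h(0) = 0``.
    """
    from scipy.stats import gamma as gamma_dist

    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("canonical_hrf requires t >= 0")
    h = gamma_dist.pdf(t_arr, peak_delay / peak_disp, scale=peak_disp) - (
        undershoot_ratio
        * gamma_dist.pdf(t_arr, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    )
    return h if np.ndim(t) else float(h)


def _hrf_kernel(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """HRF sampled at the TR, truncated at ``duration_seconds`` and scaled to
    unit peak so ``effect_amplitude`` is expressed in noise-SD units."""
    t = np.arange(0.0, duration_seconds + 1e-9, tr_seconds)
    h = np.asarray(canonical_hrf(t))
    return h / h.max()


def planted_lag_trs(tr_seconds: float = DEFAULT_TR_SECONDS) -> int:
    """The lag (in TRs) at which the sampled HRF peaks — what a lag estimator
    should recover on simulated data."""
    return int(np.argmax(_hrf_kernel(tr_seconds)))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _ar1_noise(
    rng: np.random.Generator, n_scans: int, n_voxels: int, phi: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((n_scans, n_voxels))
    out = np.empty((n_scans, n_voxels))
    out[0] = eps[0] * sd
    for i in range(1, n_scans):
        out[i] = phi * out[i - 1] + innov_sd * eps[i]
    return out


def _helmert_patterns(n_stages: int, n_voxels: int) -> np.ndarray:
    """Deterministic (n_stages, n_voxels) pattern matrix from Helmert stage
    contrasts: voxel ``j`` separates stage ``j+1`` from stages ``1..j``.

    Each column is scaled to unit standard deviation across stages so the
    planted per-voxel effect size is uniform.  With fewer voxels than
    ``n_stages - 1`` contrasts the leading contrasts are used; with more, the
    contrast set is tiled.
    """
    cols = []
    for j in range(n_voxels):
        c = np.zeros(n_stages)
        jj = j % max(n_stages - 1, 1)
        c[: jj + 1] = 1.0
        c[jj + 1] = -(jj + 1.0)
        cols.append(c / c.std())
    return np.column_stack(cols)


def _stage_regressors(
    design: TaskDesign, labels: StageLabelSeries, kernel: np.ndarray
) -> np.ndarray:
    """Stage indicators convolved with the HRF kernel: (n_scans, K)."""
    n = labels.n_scans
    out = np.empty((n, design.n_stages))
    for k in range(1, design.n_stages + 1):
        box = (labels.labels == k).astype(float)
        out[:, k - 1] = np.convolve(box, kernel)[:n]
    return out


def simulate_dataset(
    design: TaskDesign,
    rois: Sequence[RoiSpec],
    *,
    seed: int,
    global_noise_sd: float = 0.0,
    hrf_kernel: np.ndarray | None = None,
) -> SyntheticDataset:
    """Simulate labeled multivariate BOLD data for a set of ROIs.

    Per ROI: per-stage spatial patterns are drawn once (standard Gaussian over
    the informative voxels; optionally orthogonalized across stages), the
    stage indicator box-cars are convolved with the canonical HRF, the outer
    product (scaled by ``effect_amplitude``) is planted on the informative
    voxels, AR(1) noise is added, and every voxel is standardized.

    ``global_noise_sd`` > 0 adds one shared AR(1) component to every voxel of
    every ROI, emulating brain-wide BOLD fluctuations that make even
    "control" regions weakly informative.

    ``hrf_kernel`` overrides the canonical response sampled at the TR (e.g.
    ``np.array([1.0])`` plants an instantaneous, zero-lag response); the
    planted lag recorded in the ground truth is the kernel's argmax.

    The seed is mandatory: the same (design, rois, seed) reproduces the
    dataset bit for bit.
    """
    if seed is None:  # guard against an explicit None slipping through
        raise ValueError("seed is required for reproducibility")
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ValueError("ROI names must be unique")

    labels = make_design(
        design.n_trials, design.stage_durations, design.inter_trial_gap, design.tr_seconds
    )
    kernel = _hrf_kernel(design.tr_seconds) if hrf_kernel is None else np.asarray(
        hrf_kernel, dtype=float
    )
    regressors = _stage_regressors(design, labels, kernel)  # (n, K)

    root = np.random.SeedSequence(seed)
    roi_seeds = root.spawn(len(rois) + 1)
    shared = None
    if global_noise_sd > 0:
        shared_rng = np.random.default_rng(roi_seeds[-1])
        shared = _ar1_noise(shared_rng, labels.n_scans, 1, 0.4, global_noise_sd)

    out_rois: dict[str, VoxelTimeSeries] = {}
    informative: dict[str, np.ndarray] = {}
    patterns: dict[str, np.ndarray] = {}
    for spec, ss in zip(rois, roi_seeds):
        rng = np.random.default_rng(ss)
        K = design.n_stages
        pat = np.zeros((K, spec.n_informative))
        active = spec.pattern_stages(K)
        if spec.n_informative:
            if spec.pattern_strength == "unit":
                # equal per-voxel magnitude, random signs: every informative
                # voxel carries the same planted effect size
                draw = rng.choice([-1.0, 1.0], size=(len(active), spec.n_informative))
            elif spec.pattern_strength == "helmert":
                draw = _helmert_patterns(len(active), spec.n_informative)
            else:
                draw = rng.standard_normal((len(active), spec.n_informative))
            if spec.orthogonal_patterns and len(active) > 1:
                q, _ = np.linalg.qr(draw.T)
                draw = q.T[: len(active)] * np.sqrt(spec.n_informative)
            for row, stage in zip(draw, active):
                pat[stage - 1] = row
        signal = np.zeros((labels.n_scans, spec.n_voxels))
        inf_idx = np.arange(spec.n_informative)
        if spec.n_informative and spec.effect_amplitude != 0.0:
            signal[:, inf_idx] = spec.effect_amplitude * (regressors @ pat)
        noise = _ar1_noise(
            rng, labels.n_scans, spec.n_voxels, spec.ar_coefficient, spec.noise_sd
        )
        data = signal + noise
        if shared is not None:
            data = data + shared
        # per-voxel standardization, as applied to real data downstream
        data = data - data.mean(axis=0)
        sd = data.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        data = data / sd
        vids = np.array([f"{spec.name}:{i}" for i in range(spec.n_voxels)])
        out_rois[spec.name] = VoxelTimeSeries(
            data=data, tr_seconds=design.tr_seconds, voxel_ids=vids, roi=spec.name
        )
        informative[spec.name] = vids[inf_idx] if spec.n_informative else np.array([], dtype=vids.dtype)
        patterns[spec.name] = pat

    truth = GroundTruth(
        informative_voxels=informative,
        lag_trs=int(np.argmax(kernel)),
        stage_patterns=patterns,
    )
    return SyntheticDataset(rois=out_rois, labels=labels, ground_truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------


def measured_separation(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    stages_a: Sequence[int],
    stages_b: Sequence[int],
    voxel_ids: Sequence[str],
    lag_trs: int | None = None,
) -> float:
    """Mean per-voxel two-class separation |mu_a - mu_b| / pooled SD over the
    given voxels, after shifting labels by the planted lag."""
    from .prep import shift_labels

    if lag_trs is None:
        lag_trs = planted_lag_trs(ts.tr_seconds)
    shifted = shift_labels(labels, lag_trs)
    in_a = np.isin(shifted.labels, list(stages_a))
    in_b = np.isin(shifted.labels, list(stages_b))
    cols = [int(np.flatnonzero(ts.voxel_ids == v)[0]) for v in voxel_ids]
    x = ts.data[:, cols]
    mu_a, mu_b = x[in_a].mean(axis=0), x[in_b].mean(axis=0)
    var_a = x[in_a].var(axis=0, ddof=1)
    var_b = x[in_b].var(axis=0, ddof=1)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    pooled_sd = np.sqrt(((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2))
    return float(np.mean(np.abs(mu_a - mu_b) / pooled_sd))


def calibrate_amplitude(
    design: TaskDesign,
    spec: RoiSpec,
    stages_a: Sequence[int],
    stages_b: Sequence[int],
    target_separation: float,
    *,
    seed: int,
    n_reps: int = 5,
) -> float:
    """Find the effect amplitude whose mean informative-voxel two-class
    separation equals ``target_separation`` pooled-SD units.

    Separation is measured on ``n_reps`` simulated datasets and the amplitude
    solved by bisection; used to set up planted-recovery benchmarks at a
    controlled signal strength.
    """
    from dataclasses import replace as _replace

    def sep_at(amp: float) -> float:
        vals = []
        s = _replace(spec, effect_amplitude=amp)
        for r in range(n_reps):
            ds = simulate_dataset(design, [s], seed=seed + r)
            roi = ds.rois[s.name]
            vals.append(
                measured_separation(
                    roi, ds.labels, stages_a, stages_b,
                    ds.ground_truth.informative_voxels[s.name],
                )
            )
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    while sep_at(hi) < target_separation:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("calibration failed to bracket the target")
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if sep_at(mid) < target_separation:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Canonical benchmark configurations
# ---------------------------------------------------------------------------
#
# Reference setups used by the test-bench and the reproduction script; fixed
# once so results are comparable across runs.  Amplitudes are either stated
# directly (strong-signal regimes) or calibrated to a stated per-voxel
# separation via calibrate_amplitude.


def lag_benchmark() -> tuple[TaskDesign, list[RoiSpec]]:
    """Design and ROI for hemodynamic-lag recovery: a strongly activated,
    cleanly staged region.

    Uses heterogeneous stage durations (evidence epochs 2 TRs, response and
    rating 3 TRs): with all epochs equal to the lag grid the lag is only
    identifiable up to a whole epoch, since shifting labels by one epoch
    relabels stages consistently.
    """
    design = TaskDesign(
        n_trials=DEFAULT_N_TRIALS,
        stage_durations=(2, 2, 2, 2, 3, 3),
        inter_trial_gap=DEFAULT_GAP_TRS,
        tr_seconds=DEFAULT_TR_SECONDS,
    )
    roi = RoiSpec(
        name="signal",
        n_voxels=40,
        n_informative=20,
        effect_amplitude=2.0,
        orthogonal_patterns=True,
    )
    return design, [roi]


def null_benchmark(n_voxels: int = 16) -> tuple[TaskDesign, list[RoiSpec]]:
    """Zero-amplitude (pure AR(1) noise) ROI for type-I-error calibration."""
    return default_design(), [RoiSpec(name="null", n_voxels=n_voxels)]


def selection_benchmark(
    *,
    n_voxels: int = 100,
    n_informative: int = 5,
    target_separation: float = 1.5,
    calibration_seed: int = 424243,
) -> tuple[TaskDesign, list[RoiSpec], float]:
    """Planted-recovery setup: ``n_informative`` stage-coding voxels among
    ``n_voxels``, amplitude calibrated so the mean per-voxel separation
    between the first evidence stage and the decision stage (1 vs 4) is
    ``target_separation`` pooled-SD units.

    The planted voxels carry Helmert-contrast stage codes: each voxel
    separates a distinct subset of stages, so the full set is needed for
    complete six-way discrimination and "recovered k of m" is a well-posed
    score.  Uses 3-TR stage epochs (more labeled scans stabilize the
    leave-one-out error of the search); recovery is scored with the strong
    penalty ``xi = 1``, under which pure-noise inputs select nothing.
    Returns (design, rois, calibrated_amplitude).
    """
    from dataclasses import replace as _replace

    design = TaskDesign(
        n_trials=DEFAULT_N_TRIALS,
        stage_durations=(3,) * DEFAULT_N_STAGES,
        inter_trial_gap=DEFAULT_GAP_TRS,
        tr_seconds=DEFAULT_TR_SECONDS,
    )
    base = RoiSpec(
        name="planted",
        n_voxels=n_voxels,
        n_informative=n_informative,
        effect_amplitude=1.0,
        pattern_strength="helmert",
    )
    amp = calibrate_amplitude(
        design, base, (1,), (4,), target_separation, seed=calibration_seed
    )
    return design, [_replace(base, effect_amplitude=amp)], amp


def crossover_benchmark(
    effect_amplitude: float = 1.2,
    n_informative: int = 5,
) -> tuple[TaskDesign, list[RoiSpec]]:
    """Two-ROI planted design for the phase-dissociation benchmark.

    ROI ``decision`` carries a pattern only in the final evidence stage (4) —
    an accumulation/decision region; ROI ``evaluation`` carries patterns only
    in the response and rating stages (5, 6) — an outcome-evaluation region.
    A correct analysis must rank the decision-making contrast above the
    evaluation contrast in the former and the reverse in the latter.

    Uses 4-TR epochs: with short epochs the decision region's hemodynamic
    tail extends far into the response stage and legitimately discriminates
    the evaluation contrast, blurring the planted dissociation.  The two
    masks are deliberately unequal (36 vs 29 voxels) as anatomical masks
    always are; the lift (posterior/prior) scoring corrects for exactly this
    asymmetry.
    """
    design = TaskDesign(
        n_trials=DEFAULT_N_TRIALS,
        stage_durations=(4,) * DEFAULT_N_STAGES,
        inter_trial_gap=DEFAULT_GAP_TRS,
        tr_seconds=DEFAULT_TR_SECONDS,
    )
    rois = [
        RoiSpec(
            name="decision",
            n_voxels=36,
            n_informative=n_informative,
            effect_amplitude=effect_amplitude,
            stage_pattern_mode=(4,),
            pattern_strength="unit",
        ),
        RoiSpec(
            name="evaluation",
            n_voxels=29,
            n_informative=n_informative,
            effect_amplitude=effect_amplitude,
            stage_pattern_mode=(5, 6),
            pattern_strength="unit",
        ),
    ]
    return design, rois


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset to disk: one 4-D NIfTI per ROI (voxels laid out along
    the first axis), labels as TSV, ground truth and config as JSON."""
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ts in ds.rois.items():
        vol = ts.data.T.reshape(ts.n_voxels, 1, 1, ts.n_scans)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        img.header["pixdim"][4] = ts.tr_seconds
        nib.save(img, outdir / f"{name}.nii")
    pd.DataFrame(
        {
            "scan_index": np.arange(ds.labels.n_scans),
            "trial_id": ds.labels.trial_ids,
            "stage_label": ds.labels.labels,
        }
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    truth = {
        "lag_trs": ds.ground_truth.lag_trs,
        "informative_voxels": {
            k: list(map(str, v)) for k, v in ds.ground_truth.informative_voxels.items()
        },
        "stage_patterns": {
            k: np.asarray(v).tolist() for k, v in ds.ground_truth.stage_patterns.items()
        },
        "seed": ds.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
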