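"""Block-permutation bootstrap significance machinery.

fMRI time series are strongly autocorrelated, so scan-wise label permutation
would destroy the very dependence structure the null distribution must
respect.  Instead, within every trial the maximal runs of identical
consecutive labels (including unlabeled runs) are extracted and their order is
permuted, preserving both the per-trial label composition and the run-length
structure — and therefore the within-run autocorrelation.

To compare ROIs of different sizes on an equal footing, every statistic is
computed as the average over ``n_draws`` random voxel subsets of a fixed size
``v`` (conventionally the size of the smallest ROI under joint analysis).
The observed subsampled statistic is referenced to ``n_bootstrap`` values of
the same quantity computed on block-permuted labels; the report carries the
ratio observed / null-mean (fold above null), a z-score, and the add-one
permutation p-value ``(1 + #{null >= observed}) / (1 + B)``.

Seeding contract: a single master seed; per-bootstrap and per-draw substreams
are derived deterministically via ``numpy.random.SeedSequence`` spawning, so
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import mvstat
from .prep import StageLabelSeries, VoxelTimeSeries

__all__ = [
    "BootstrapConfig",
    "BootstrapNull",
    "block_permutation",
    "subsampled_statistic",
    "bootstrap_null",
    "normalized_distance_matrix",
    "stat_lawley_hotelling",
    "stat_wilks_lambda",
    "stat_roy_gcr",
]

StatFn = Callable[[np.ndarray, StageLabelSeries], float]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``v = None`` means "use every voxel of the analyzed ROI" (the smallest-ROI
    convention is applied by callers that analyze several ROIs jointly).
    """

    n_bootstrap: int = 1000
    n_draws: int = 50
    v: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_draws < 1:
            raise ValueError("n_bootstrap and n_draws must be >= 1")
        if self.v is not None and self.v < 1:
            raise ValueError("v must be >= 1")


@dataclass(frozen=True)
class BootstrapNull:
    """Observed statistic with its block-permutation null distribution."""

    observed: float
    null_values: np.ndarray
    config: BootstrapConfig

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def normalized(self) -> float:
        return self.observed / self.null_mean

    @property
    def z(self) -> float:
        sd = float(np.std(self.null_values, ddof=1))
        return (self.observed - self.null_mean) / sd

    @property
    def p(self) -> float:
        b = self.null_values.size
        return (1.0 + float(np.sum(self.null_values >= self.observed))) / (1.0 + b)


# ---------------------------------------------------------------------------
# Permutation
# ---------------------------------------------------------------------------


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant-value runs as (start, stop) index pairs."""
    if values.size == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [values.size]])
    return list(zip(starts, stops))


def block_permutation(
    labels: StageLabelSeries, rng: np.random.Generator
) -> StageLabelSeries:
    """Permute, within each trial, the order of maximal constant-label runs.

    Unlabeled (label 0) runs participate in the shuffle, so the per-trial
    multiset of (label, run length) — and hence the autocorrelation scale of
    the labeling — is exactly preserved.  Data rows are never touched; only
    the label series is rearranged.
    """
    out = np.empty_like(labels.labels)
    for start, stop in _runs(labels.trial_ids):
        seg = labels.labels[start:stop]
        runs = _runs(seg)
        order = rng.permutation(len(runs))
        pos = start
        for ri in order:
            a, b = runs[ri]
            out[pos : pos + (b - a)] = seg[a:b]
            pos += b - a
    return StageLabelSeries(
        labels=out, trial_ids=labels.trial_ids, n_stages=labels.n_stages
    )


# ---------------------------------------------------------------------------
# Subsampled statistics
# ---------------------------------------------------------------------------


def stat_lawley_hotelling(data: np.ndarray, labels: StageLabelSeries) -> float:
    """Lawley-Hotelling trace (generalized T^2) on the labeled scans."""
    x = data[labels.labeled_mask]
    y = labels.labels[labels.labeled_mask]
    return mvstat.manova_stats(mvstat.scatter_from_arrays(x, y)).lawley_hotelling


def stat_wilks_lambda(data: np.ndarray, labels: StageLabelSeries) -> float:
    """Wilks' lambda.  Note it DECREASES with separation: the add-one p-value,
    which counts null values >= observed, is a left-tail test here — use the
    trace or Roy statistics (or 1 - lambda) for right-tail significance."""
    x = data[labels.labeled_mask]
    y = labels.labels[labels.labeled_mask]
    return mvstat.manova_stats(mvstat.scatter_from_arrays(x, y)).wilks_lambda


def stat_roy_gcr(data: np.ndarray, labels: StageLabelSeries) -> float:
    x = data[labels.labeled_mask]
    y = labels.labels[labels.labeled_mask]
    return mvstat.manova_stats(mvstat.scatter_from_arrays(x, y)).roy_gcr


def _draw_columns(
    rng: np.random.Generator, n_voxels: int, v: int, n_draws: int
) -> list[np.ndarray]:
    if v > n_voxels:
        raise ValueError(f"v={v} exceeds ROI size {n_voxels}")
    if v == n_voxels:
        return [np.arange(n_voxels)] * n_draws
    return [rng.choice(n_voxels, size=v, replace=False) for _ in range(n_draws)]


def subsampled_statistic(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    stat_fn: StatFn,
    cfg: BootstrapConfig,
    rng: np.random.Generator,
) -> float:
    """Mean of ``stat_fn`` over ``n_draws`` random voxel subsets of size ``v``
    (without replacement within a draw)."""
    v = cfg.v if cfg.v is not None else ts.n_voxels
    cols = _draw_columns(rng, ts.n_voxels, v, cfg.n_draws)
    return float(np.mean([stat_fn(ts.data[:, c], labels) for c in cols]))


def bootstrap_null(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    stat_fn: StatFn,
    cfg: BootstrapConfig,
    rng: np.random.Generator | int | None = None,
) -> BootstrapNull:
    """Observed subsampled statistic plus its block-permutation null.

    Each of the ``n_bootstrap`` null values is the subsampled statistic on an
    independent within-trial block permutation of the labels.
    """
    if isinstance(rng, np.random.Generator):
        streams = rng.spawn(cfg.n_bootstrap + 1)
    else:
        master = cfg.seed if rng is None else int(rng)
        streams = [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(master).spawn(cfg.n_bootstrap + 1)
        ]

    observed = subsampled_statistic(ts, labels, stat_fn, cfg, streams[0])
    null = np.empty(cfg.n_bootstrap)
    for b in range(cfg.n_bootstrap):
        perm_rng = streams[b + 1]
        perm = block_permutation(labels, perm_rng)
        null[b] = subsampled_statistic(ts, perm, stat_fn, cfg, perm_rng)
    return BootstrapNull(observed=observed, null_values=null, config=cfg)


# ---------------------------------------------------------------------------
# Normalized stage-distance matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizedDistances:
    """Pairwise stage distances normalized by pair-specific nulls."""

    observed: mvstat.StageDistanceMatrix
    normalized: mvstat.StageDistanceMatrix
    p_values: np.ndarray
    config: BootstrapConfig


def _subsampled_d2(
    ts_data: np.ndarray,
    labels: StageLabelSeries,
    lambda_reg: float,
    cols_list: Sequence[np.ndarray],
    tr_seconds: float,
) -> np.ndarray:
    from .prep import VoxelTimeSeries as VTS

    acc = None
    for c in cols_list:
        sub = VTS(
            data=ts_data[:, c],
            tr_seconds=tr_seconds,
            voxel_ids=np.arange(len(c)),
        )
        d2 = mvstat.stage_distance_matrix(sub, labels, lambda_reg).d2
        acc = d2 if acc is None else acc + d2
    return acc / len(cols_list)


def normalized_distance_matrix(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = mvstat.DEFAULT_SHRINKAGE,
    cfg: BootstrapConfig = BootstrapConfig(),
    rng: int | None = None,
) -> NormalizedDistances:
    """Stage-distance matrix with each pair normalized by its own null.

    Every stage pair is divided by the mean of *its own* permutation
    distribution, which compensates both for autocorrelation and for the
    different temporal separations between stage pairs; per-pair add-one
    p-values are reported alongside.
    """
    master = cfg.seed if rng is None else rng
    seeds = np.random.SeedSequence(master).spawn(cfg.n_bootstrap + 1)
    v = cfg.v if cfg.v is not None else ts.n_voxels

    rng0 = np.random.default_rng(seeds[0])
    cols = _draw_columns(rng0, ts.n_voxels, v, cfg.n_draws)
    obs = _subsampled_d2(ts.data, labels, lambda_reg, cols, ts.tr_seconds)

    K = labels.n_stages
    null = np.empty((cfg.n_bootstrap, K, K))
    for b in range(cfg.n_bootstrap):
        rng_b = np.random.default_rng(seeds[b + 1])
        perm = block_permutation(labels, rng_b)
        cols_b = _draw_columns(rng_b, ts.n_voxels, v, cfg.n_draws)
        null[b] = _subsampled_d2(ts.data, perm, lambda_reg, cols_b, ts.tr_seconds)

    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(null_mean > 0, obs / null_mean, 0.0)
    np.fill_diagonal(norm, 0.0)
    p = (1.0 + np.sum(null >= obs[None], axis=0)) / (1.0 + cfg.n_bootstrap)
    np.fill_diagonal(p, 1.0)
    return NormalizedDistances(
        observed=mvstat.StageDistanceMatrix(d2=obs, n_stages=K),
        normalized=mvstat.StageDistanceMatrix(d2=norm, n_stages=K),
        p_values=p,
        config=cfg,
    )
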