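"""Time-series preparation: containers, discard, detrend/high-pass/standardize,
hemodynamic-lag estimation by canonical correlation, and label shifting.

The central containers are :class:`VoxelTimeSeries` (a scans x voxels matrix for
one region of interest) and :class:`StageLabelSeries` (one stage label and one
trial id per scan; label 0 marks unlabeled/control scans).  All downstream
statistics operate on these two objects.

Preprocessing follows the convention used for blocked fMRI designs: per-voxel
linear detrend, removal of slow drifts via a discrete-cosine basis (all
components with period longer than the high-pass cutoff), then z-scoring, so
every surviving voxel leaves this module with mean 0 and unit variance.

The BOLD response lags the eliciting neural event by several seconds.  Rather
than assuming a lag, :func:`estimate_lag` scans candidate lags (in TRs) and
picks the one maximizing the first canonical correlation between the voxel
time series and a stage-indicator coding of the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelTimeSeries",
    "StageLabelSeries",
    "LagEstimate",
    "discard_initial",
    "preprocess",
    "estimate_lag",
    "shift_labels",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelTimeSeries:
    """A scans x voxels BOLD matrix for one ROI.

    Parameters
    ----------
    data:
        Real matrix of shape ``(n_scans, n_voxels)``.
    tr_seconds:
        Sampling interval (repetition time) in seconds.
    voxel_ids:
        Stable per-voxel identifiers (used to report selections and to map
        voxels back to ROIs).  Unique within the object.
    roi:
        Name of the region of interest the voxels belong to.
    subject_id:
        Free-text subject identifier.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_ids: np.ndarray
    roi: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D scans x voxels matrix")
        vids = np.asarray(self.voxel_ids)
        if vids.shape[0] != data.shape[1]:
            raise ValueError(
                f"voxel_ids length {vids.shape[0]} does not match "
                f"voxel count {data.shape[1]}"
            )
        if len(set(vids.tolist())) != vids.shape[0]:
            raise ValueError("voxel_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_ids", vids)

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class StageLabelSeries:
    """Per-scan stage labels (0..K, 0 = unlabeled) plus trial ids.

    ``trial_ids`` define the block structure that the block-permutation
    bootstrap shuffles within; they must be non-decreasing.
    """

    labels: np.ndarray
    trial_ids: np.ndarray
    n_stages: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        trials = np.asarray(self.trial_ids, dtype=int)
        if labels.ndim != 1 or trials.ndim != 1:
            raise ValueError("labels and trial_ids must be 1-D")
        if labels.shape != trials.shape:
            raise ValueError("labels and trial_ids must have equal length")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() > self.n_stages):
            raise ValueError(f"labels must lie in 0..{self.n_stages}")
        if np.any(np.diff(trials) < 0):
            raise ValueError("trial_ids must be non-decreasing")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "trial_ids", trials)

    @property
    def n_scans(self) -> int:
        return self.labels.shape[0]

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class LagEstimate:
    """Result of hemodynamic-lag estimation.

    ``lag_trs`` is the argmax of ``correlation_profile``, the canonical
    association ``1 - prod(1 - rho_i^2)`` over all canonical correlations
    between the lag-shifted stage indicators and the time series at each
    candidate lag 0..max_lag.
    ``first_canonical_profile`` carries the largest canonical correlation per
    lag for reference; it is not used for the argmax because a single maximal
    direction saturates near 1 at every lag on smeared hemodynamic data.
    """

    lag_trs: int
    correlation_profile: np.ndarray
    first_canonical_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        prof = np.asarray(self.correlation_profile, dtype=float)
        object.__setattr__(self, "correlation_profile", prof)
        if int(np.argmax(prof)) != self.lag_trs:
            raise ValueError("lag_trs must be the argmax of the profile")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def discard_initial(
    ts: VoxelTimeSeries, labels: StageLabelSeries, k: int
) -> tuple[VoxelTimeSeries, StageLabelSeries]:
    """Drop the first ``k`` scans (magnetic-saturation volumes) jointly from
    data and labels."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_scans:
        raise ValueError(f"cannot discard {k} of {ts.n_scans} scans")
    if labels.n_scans != ts.n_scans:
        raise ValueError("labels and time series disagree on scan count")
    if k == 0:
        return ts, labels
    new_ts = replace(ts, data=ts.data[k:])
    new_labels = StageLabelSeries(
        labels=labels.labels[k:], trial_ids=labels.trial_ids[k:], n_stages=labels.n_stages
    )
    return new_ts, new_labels


def dct_drift_basis(n_scans: int, tr_seconds: float, cutoff_seconds: float) -> np.ndarray:
    """Discrete-cosine drift regressors: all DCT components with period longer
    than ``cutoff_seconds``.

    Component ``j`` (j >= 1) is ``cos(pi * j * (2t + 1) / (2N))`` with period
    ``2 * N * TR / j``; the basis contains every j with period > cutoff.
    Returns an ``(n_scans, n_components)`` array (possibly empty).
    """
    total = 2.0 * n_scans * tr_seconds
    n_comp = int(np.floor(total / cutoff_seconds))  # j < total/cutoff
    if total / max(n_comp, 1) <= cutoff_seconds:
        n_comp -= 1
    n_comp = max(n_comp, 0)
    t = np.arange(n_scans)
    cols = [
        np.cos(np.pi * j * (2 * t + 1) / (2.0 * n_scans)) for j in range(1, n_comp + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def preprocess(
    ts: VoxelTimeSeries,
    cutoff_seconds: float = 256.0,
    degenerate_tol: float = 1e-12,
) -> VoxelTimeSeries:
    """Detrend, high-pass filter and standardize every voxel.

    Per voxel: (1) remove a linear trend, (2) regress out discrete-cosine
    drift components with period > ``cutoff_seconds``, (3) z-score.  Voxels
    whose residual variance is (numerically) zero after filtering cannot be
    standardized; they are dropped with a logged warning rather than being
    silently zero-filled.
    """
    if ts.n_scans < 3:
        raise ValueError("preprocess requires at least 3 scans")
    if cutoff_seconds <= 0:
        raise ValueError("cutoff_seconds must be positive")

    n = ts.n_scans
    t = np.arange(n, dtype=float)
    # joint regression basis: intercept + linear trend + DCT drift set
    drift = dct_drift_basis(n, ts.tr_seconds, cutoff_seconds)
    basis = np.column_stack([np.ones(n), t - t.mean(), drift])
    q, _ = np.linalg.qr(basis)
    resid = ts.data - q @ (q.T @ ts.data)

    sd = resid.std(axis=0, ddof=0)
    keep = sd > degenerate_tol * max(1.0, float(np.abs(ts.data).max()))
    if not np.all(keep):
        dropped = ts.voxel_ids[~keep]
        logger.warning(
            "preprocess: dropping %d degenerate voxel(s) with zero residual "
            "variance in ROI %r: %s",
            dropped.size,
            ts.roi,
            dropped.tolist(),
        )
    if not np.any(keep):
        raise ValueError("all voxels degenerate after filtering")
    out = resid[:, keep] / sd[keep]
    return replace(ts, data=out, voxel_ids=ts.voxel_ids[keep])


def _canonical_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All canonical correlations between column-centered matrices via QR/SVD."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    qx, rx = np.linalg.qr(xc)
    qy, ry = np.linalg.qr(yc)
    # guard rank deficiency: drop numerically null columns
    keep_x = np.abs(np.diag(rx)) > 1e-10 * max(1.0, np.abs(np.diag(rx)).max())
    keep_y = np.abs(np.diag(ry)) > 1e-10 * max(1.0, np.abs(np.diag(ry)).max())
    qx = qx[:, keep_x]
    qy = qy[:, keep_y]
    if qx.shape[1] == 0 or qy.shape[1] == 0:
        return np.zeros(1)
    s = scipy.linalg.svd(qx.T @ qy, compute_uv=False)
    return np.minimum(1.0, s)


def _reduce_dimension(data: np.ndarray, max_components: int) -> np.ndarray:
    """Project onto leading principal components explaining 95% of variance,
    capped at ``max_components``."""
    centered = data - data.mean(axis=0)
    u, s, _ = scipy.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        return centered[:, :1]
    n_keep = int(np.searchsorted(np.cumsum(var) / total, 0.95) + 1)
    n_keep = min(n_keep, max_components, s.size)
    n_keep = max(n_keep, 1)
    return u[:, :n_keep] * s[:n_keep]


def estimate_lag(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    max_lag_trs: int = 5,
) -> LagEstimate:
    """Estimate the hemodynamic lag (in TRs) by canonical correlation.

    For each candidate lag the labels are shifted forward in time, a
    stage-indicator matrix (K binary columns, one dropped against the
    intercept) is formed over the labeled scans, and the canonical
    correlations ``rho_i`` against the dimension-reduced time series are
    computed.  The returned lag maximizes the canonical association
    ``1 - prod(1 - rho_i^2)``, which pools the whole canonical spectrum; the
    first canonical correlation alone is uninformative here because one
    maximal direction is found at every candidate lag once the hemodynamic
    response smears stage patterns into their neighbors.

    The voxel matrix is reduced to principal components explaining 95% of
    variance, capped at one tenth of the labeled scan count: a looser cap
    lets spurious canonical directions flatten the lag profile.

    Note that with stage epochs of exactly equal length the lag is only
    identifiable up to a whole epoch (shifting labels by one epoch relabels
    stages consistently); designs with heterogeneous epoch durations do not
    suffer this aliasing.
    """
    if max_lag_trs < 0:
        raise ValueError("max_lag_trs must be non-negative")
    if not np.any(labels.labeled_mask):
        raise ValueError("estimate_lag requires at least one labeled scan")
    n_labeled = int(labels.labeled_mask.sum())
    if n_labeled < 10 * labels.n_stages:
        raise ValueError(
            f"estimate_lag requires >= 10 x K labeled scans "
            f"(got {n_labeled} for K={labels.n_stages})"
        )

    profile = np.zeros(max_lag_trs + 1)
    first = np.zeros(max_lag_trs + 1)
    for lag in range(max_lag_trs + 1):
        shifted = shift_labels(labels, lag)
        mask = shifted.labeled_mask
        if mask.sum() < labels.n_stages + 2:
            continue
        x = ts.data[mask]
        lab = shifted.labels[mask]
        x = _reduce_dimension(x, max_components=max(1, mask.sum() // 10))
        # K indicator columns with the last dropped (centering absorbs it)
        y = np.column_stack(
            [(lab == k).astype(float) for k in range(1, labels.n_stages)]
        )
        rho = _canonical_correlations(x, y)
        profile[lag] = float(1.0 - np.prod(1.0 - rho**2))
        first[lag] = float(rho[0])
    return LagEstimate(
        lag_trs=int(np.argmax(profile)),
        correlation_profile=profile,
        first_canonical_profile=first,
    )


def shift_labels(labels: StageLabelSeries, lag_trs: int) -> StageLabelSeries:
    """Shift labels forward by ``lag_trs`` scans to compensate hemodynamic lag.

    The label of stimulus scan ``i`` is applied to scan ``i + lag``; the first
    ``lag`` scans become unlabeled and trailing labels fall off the end.
    Trial ids are shifted the same way, with the leading gap filled by the
    first trial id so the non-decreasing invariant holds.
    """
    if lag_trs < 0:
        raise ValueError("lag_trs must be non-negative")
    n = labels.n_scans
    if lag_trs >= n and lag_trs > 0:
        raise ValueError(f"lag {lag_trs} >= series length {n}")
    if lag_trs == 0:
        return labels
    new_labels = np.zeros(n, dtype=int)
    new_labels[lag_trs:] = labels.labels[: n - lag_trs]
    new_trials = np.empty(n, dtype=int)
    new_trials[lag_trs:] = labels.trial_ids[: n - lag_trs]
    new_trials[:lag_trs] = labels.trial_ids[0]
    return StageLabelSeries(labels=new_labels, trial_ids=new_trials, n_stages=labels.n_stages)
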