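"""Penalized-cross-validation voxel selection.

A minimum-Mahalanobis regularized-LDA classifier assigns a scan's activity
pattern ``x_i`` over a voxel set S to the stage ``k`` minimizing
``delta_k(x_i) = (x_i - mu_k) sigma_hat^-1 (x_i - mu_k)^T``.  The quality of S
is its leave-one-out cross-validation error CVE(S): the fraction of scans
misclassified when each is predicted by a classifier fit without it.  Larger
sets are penalized through

    PCV(S) = CVE(S) * (1 + xi * p / log n)

with p = |S|, n the number of labeled scans and ``xi`` a penalty constant.

The search is greedy: forward addition of the voxel giving the lowest CVE
until the PCV stops decreasing, then backward deletion while the PCV is
non-increasing.  Selected voxels are attributed back to their ROIs and the
per-subject consistency of ROI preferences is assessed with an exact
binomial sign test.

Leave-one-out errors are computed by an exact rank-one downdate of the class
means and within-class scatter (algebraically identical to refitting the
classifier without the held-out scan), batched over scans with stacked linear
algebra; a naive refit loop is kept in the test suite as the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.stats

from . import mvstat
from .prep import StageLabelSeries, VoxelTimeSeries

__all__ = [
    "LdaModel",
    "SelectionEvent",
    "SelectionTrace",
    "RoiAttribution",
    "lda_fit",
    "lda_classify",
    "loo_cve",
    "pcv",
    "forward_backward_select",
    "roi_attribution",
    "sign_test",
    "phase_labels",
]

DEFAULT_XI = 0.1


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LdaModel:
    """Minimum-Mahalanobis LDA: class means plus a shared regularized pooled
    covariance.  Class order is fixed and recorded; distance ties break toward
    the earliest class in ``class_ids``."""

    class_means: np.ndarray  # (K, p)
    cov: mvstat.RegularizedCovariance
    class_ids: np.ndarray


def lda_fit(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = mvstat.DEFAULT_SHRINKAGE,
) -> LdaModel:
    """Fit the classifier on the labeled scans of ``ts``."""
    sp = mvstat.scatter_matrices(ts, labels)
    cov = mvstat.regularized_cov_from_scatter(sp, lambda_reg)
    return LdaModel(class_means=sp.class_means, cov=cov, class_ids=sp.class_ids)


def lda_classify(model: LdaModel, x: np.ndarray) -> int | np.ndarray:
    """Assign pattern(s) to the class of minimum Mahalanobis distance.

    Accepts a single p-vector or an (m, p) batch; returns class id(s).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None] if single else x
    if not np.all(np.isfinite(xb)):
        raise ValueError("patterns must be finite")
    p = model.class_means.shape[1]
    if xb.shape[1] != p:
        raise ValueError(f"pattern dimension {xb.shape[1]} != model dimension {p}")
    L = model.cov.cholesky()
    zm = scipy.linalg.solve_triangular(L, model.class_means.T, lower=True).T  # (K, p)
    zx = scipy.linalg.solve_triangular(L, xb.T, lower=True).T  # (m, p)
    diff = zx[:, None, :] - zm[None, :, :]
    d2 = np.einsum("mkp,mkp->mk", diff, diff)
    idx = np.argmin(d2, axis=1)  # first occurrence = earliest class on ties
    out = model.class_ids[idx]
    return int(out[0]) if single else out


# ---------------------------------------------------------------------------
# Leave-one-out CVE
# ---------------------------------------------------------------------------


def _check_classes(y: np.ndarray, min_count: int) -> tuple[np.ndarray, np.ndarray]:
    class_ids, counts = np.unique(y, return_counts=True)
    if class_ids.size < 2:
        raise ValueError("need at least 2 classes")
    small = class_ids[counts < min_count]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than {min_count} scans"
        )
    return class_ids, counts


def _loo_errors(x: np.ndarray, y: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Boolean misclassification flags for every labeled scan under exact
    leave-one-out, via batched downdates of means and scatter."""
    n, p = x.shape
    class_ids, counts = _check_classes(y, min_count=3)
    K = class_ids.size
    dof = n - 1 - K
    if dof < 1:
        raise ValueError("too few scans for leave-one-out pooled covariance")
    inv_map = np.searchsorted(class_ids, y)
    sums = np.zeros((K, p))
    np.add.at(sums, inv_map, x)
    means = sums / counts[:, None]
    resid = x - means[inv_map]
    E = resid.T @ resid

    # downdated within-class scatter per held-out scan
    f = (counts / (counts - 1.0))[inv_map]  # n_c / (n_c - 1)
    E_i = E[None] - f[:, None, None] * np.einsum("ip,iq->ipq", resid, resid)
    sigma = E_i / dof
    sigma_hat = (1.0 - lambda_reg) * sigma
    d_idx = np.arange(p)
    sigma_hat[:, d_idx, d_idx] = sigma[:, d_idx, d_idx]

    # downdated class means: only the held-out scan's own class changes
    diffs = x[:, None, :] - means[None, :, :]  # (n, K, p)
    own = (sums[inv_map] - x) / (counts[inv_map] - 1.0)[:, None]
    diffs[np.arange(n), inv_map] = x - own

    inv = np.linalg.inv(sigma_hat)
    d2 = np.einsum("nkp,npq,nkq->nk", diffs, inv, diffs)
    pred = class_ids[np.argmin(d2, axis=1)]
    return pred != y


def loo_cve(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = mvstat.DEFAULT_SHRINKAGE,
) -> float:
    """Leave-one-out cross-validation error of the LDA classifier.

    Every labeled scan is classified by a model fit on all other labeled
    scans; the returned value is the misclassified fraction, in [0, 1].
    Requires every class to have at least 3 scans so no leave-one-out fold
    empties a class.
    """
    mask = labels.labeled_mask
    x = ts.data[mask]
    y = labels.labels[mask]
    if x.shape[0] == 0:
        raise ValueError("no labeled scans")
    return float(np.mean(_loo_errors(x, y, lambda_reg)))


def pcv(cve: float, p: int, n: float, xi: float = DEFAULT_XI) -> float:
    """Penalized cross-validation error ``CVE * (1 + xi * p / log n)``
    (natural logarithm)."""
    if n < 2:
        raise ValueError("pcv requires n >= 2")
    if p < 0:
        raise ValueError("p must be non-negative")
    if xi < 0:
        raise ValueError("xi must be non-negative")
    return cve * (1.0 + xi * p / math.log(n))


# ---------------------------------------------------------------------------
# Forward-backward search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionEvent:
    action: str  # "add" | "remove"
    voxel_id: str
    cve: float
    pcv: float


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered add/remove events with the CVE/PCV after each step, the final
    voxel set, and the run parameters."""

    events: tuple[SelectionEvent, ...]
    final_set: tuple[str, ...]
    xi: float
    n: int
    lambda_reg: float
    pcv_empty: float
    converged: bool = True

    @property
    def final_cve(self) -> float:
        for ev in reversed(self.events):
            return ev.cve
        return self.pcv_empty  # empty selection: baseline error

    @property
    def final_pcv(self) -> float:
        for ev in reversed(self.events):
            return ev.pcv
        return self.pcv_empty

    def replay_final_set(self) -> tuple[str, ...]:
        """Reconstruct the final set from the event list (trace consistency)."""
        current: list[str] = []
        for ev in self.events:
            if ev.action == "add":
                current.append(ev.voxel_id)
            else:
                current.remove(ev.voxel_id)
        return tuple(sorted(current))


def forward_backward_select(
    ts: VoxelTimeSeries,
    labels: StageLabelSeries,
    lambda_reg: float = mvstat.DEFAULT_SHRINKAGE,
    xi: float = DEFAULT_XI,
    max_steps: int | None = None,
) -> SelectionTrace:
    """Greedy forward-addition / backward-deletion voxel selection.

    Forward phase: at each step the candidate voxel whose addition yields the
    lowest CVE is identified (ties break toward the lowest-index voxel) and
    added while this strictly decreases the PCV; the phase stops at the first
    non-improving candidate.  The empty-set baseline is
    ``PCV(empty) = 1 - max_k n_k / n`` (the error of always guessing the
    majority stage).

    Backward phase: single-voxel deletions are ranked by the PCV they would
    produce and applied while the PCV is non-increasing.

    A ``max_steps`` cap (default: voxel count) guards runaway searches; a
    truncated forward phase is flagged ``converged=False``.
    """
    mask = labels.labeled_mask
    x = ts.data[mask]
    y = labels.labels[mask]
    if x.shape[0] == 0:
        raise ValueError("no labeled scans")
    _check_classes(y, min_count=3)
    n = x.shape[0]
    n_vox = x.shape[1]
    if max_steps is None:
        max_steps = n_vox
    vids = [str(v) for v in ts.voxel_ids]

    _, counts = np.unique(y, return_counts=True)
    pcv_empty = pcv(1.0 - counts.max() / n, 0, n, xi)

    selected: list[int] = []
    events: list[SelectionEvent] = []
    current_pcv = pcv_empty
    converged = True

    # forward phase
    while len(selected) < max_steps:
        candidates = [j for j in range(n_vox) if j not in selected]
        if not candidates:
            break
        cves = np.array(
            [float(np.mean(_loo_errors(x[:, selected + [j]], y, lambda_reg)))
             for j in candidates]
        )
        best_pos = int(np.argmin(cves))  # first occurrence = lowest voxel index
        best_j = candidates[best_pos]
        best_cve = float(cves[best_pos])
        new_pcv = pcv(best_cve, len(selected) + 1, n, xi)
        if new_pcv >= current_pcv:
            break
        selected.append(best_j)
        current_pcv = new_pcv
        events.append(SelectionEvent("add", vids[best_j], best_cve, new_pcv))
    else:
        if len(selected) == max_steps and max_steps < n_vox:
            converged = False

    # backward phase: rank deletions by resulting PCV
    while selected:
        options = []
        for j in selected:
            rest = [k for k in selected if k != j]
            if rest:
                cve_j = float(np.mean(_loo_errors(x[:, rest], y, lambda_reg)))
                pcv_j = pcv(cve_j, len(rest), n, xi)
            else:
                cve_j = 1.0 - counts.max() / n
                pcv_j = pcv_empty
            options.append((pcv_j, j, cve_j))
        best_pcv, best_j, best_cve = min(options, key=lambda t: (t[0], t[1]))
        if best_pcv <= current_pcv:
            selected.remove(best_j)
            current_pcv = best_pcv
            events.append(SelectionEvent("remove", vids[best_j], best_cve, best_pcv))
        else:
            break

    return SelectionTrace(
        events=tuple(events),
        final_set=tuple(sorted(vids[j] for j in selected)),
        xi=xi,
        n=n,
        lambda_reg=lambda_reg,
        pcv_empty=pcv_empty,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# ROI attribution and sign test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiAttribution:
    """Where the selected voxels came from, against the mask-size priors.

    ``lift = posterior / prior`` exceeds 1 when an ROI contributes more
    selected voxels than its share of the candidate mask would predict.
    """

    counts: dict[str, int]
    priors: dict[str, float]
    posteriors: dict[str, float]
    lifts: dict[str, float]


def roi_attribution(
    trace: SelectionTrace | Sequence[str],
    roi_of_voxel: Mapping[str, str],
    mask_sizes: Mapping[str, int],
) -> RoiAttribution:
    """Attribute selected voxels to ROIs and compare with mask-size priors."""
    selected = list(trace.final_set) if isinstance(trace, SelectionTrace) else list(trace)
    unmapped = [v for v in selected if v not in roi_of_voxel]
    if unmapped:
        raise ValueError(f"selected voxel(s) not mapped to any ROI: {unmapped}")
    total_mask = sum(mask_sizes.values())
    if total_mask <= 0:
        raise ValueError("mask sizes must sum to a positive count")
    counts = {r: 0 for r in mask_sizes}
    for v in selected:
        r = roi_of_voxel[v]
        if r not in counts:
            raise ValueError(f"voxel {v!r} maps to unknown ROI {r!r}")
        counts[r] += 1
    priors = {r: mask_sizes[r] / total_mask for r in mask_sizes}
    n_sel = len(selected)
    posteriors = {r: (counts[r] / n_sel if n_sel else 0.0) for r in mask_sizes}
    lifts = {r: (posteriors[r] / priors[r] if priors[r] > 0 else 0.0) for r in mask_sizes}
    return RoiAttribution(counts=counts, priors=priors, posteriors=posteriors, lifts=lifts)


def sign_test(n_success: int, n: int) -> float:
    """Exact two-sided binomial (sign) test at rate 1/2."""
    if not 0 <= n_success <= n:
        raise ValueError("need 0 <= n_success <= n")
    return float(scipy.stats.binomtest(n_success, n, 0.5).pvalue)


def phase_labels(labels: StageLabelSeries, phase: str) -> StageLabelSeries:
    """Regroup 6-stage labels into a two-class task-phase contrast.

    ``"making"``: evidence stages 1-3 become class 1, the final (fourth)
    evidence stage becomes class 2 — accumulation vs the decision point.
    ``"evaluation"``: stages 1-3 become class 1, the behavioral-response and
    choice-rating stages (5, 6) become class 2 — accumulation vs outcome
    evaluation.  All other scans become unlabeled.
    """
    if labels.n_stages != 6:
        raise ValueError("phase_labels is specific to the 6-stage design")
    lab = labels.labels
    out = np.zeros_like(lab)
    out[np.isin(lab, (1, 2, 3))] = 1
    if phase == "making":
        out[lab == 4] = 2
    elif phase == "evaluation":
        out[np.isin(lab, (5, 6))] = 2
    else:
        raise ValueError("phase must be 'making' or 'evaluation'")
    return StageLabelSeries(labels=out, trial_ids=labels.trial_ids, n_stages=2)
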