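"""Winner-take-all mesoscopic clusters and group-level condition comparisons.

Voxels are assigned to the horizontal (H) cluster when their t value for the
horizontal > vertical contrast exceeds the 95th percentile of in-ROI t values,
and to the vertical (V) cluster when it falls below the 5th percentile
(equivalently, the 95th percentile of the reversed contrast).  Percentiles are
computed within each ROI per hemisphere with linear interpolation; ties at the
threshold are excluded (strict inequality), keeping each cluster at most 5% of
the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from lamiquartet.stats import GroupComparison, UndefinedTestError, wilcoxon_signed_rank


class DegenerateClusterError(ValueError):
    """The ROI cannot support percentile-separated clusters."""


class MissingDataError(ValueError):
    """A required record (motion parameters, cluster cell) is absent."""


@dataclass
class ClusterAssignment:
    """Per-voxel H/V/none labels with the thresholds that produced them."""

    labels: np.ndarray  # 'H' | 'V' | 'none' per voxel
    t_high: float
    t_low: float
    pct: float
    roi: str = ""

    def members(self, cluster: str) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def define_clusters(
    tmap: np.ndarray,
    roi_mask: np.ndarray | None = None,
    pct: float = 95.0,
    roi: str = "",
) -> ClusterAssignment:
    """Threshold a contrast t-map into winner-take-all H and V clusters.

    H voxels have t strictly above the ``pct``-th percentile of in-ROI t; V
    voxels strictly below the ``100 - pct``-th percentile; the rest are
    unassigned.  Raises :class:`DegenerateClusterError` when the ROI is too
    small for the percentile tail or all t values coincide.
    """
    tmap = np.asarray(tmap, dtype=float)
    if not 50 < pct < 100:
        raise ValueError(f"pct must lie in (50, 100), got {pct}")
    mask = np.ones(len(tmap), bool) if roi_mask is None else np.asarray(roi_mask, bool)
    t_roi = tmap[mask]
    min_n = int(np.ceil(1.0 / (1.0 - pct / 100.0)))
    if len(t_roi) < min_n:
        raise DegenerateClusterError(f"ROI of {len(t_roi)} voxels cannot resolve the {pct}th percentile")
    if np.ptp(t_roi) == 0:
        raise DegenerateClusterError("all t values equal; no percentile separation")
    t_high = float(np.percentile(t_roi, pct))
    t_low = float(np.percentile(t_roi, 100.0 - pct))
    labels = np.full(len(tmap), "none", dtype=object)
    labels[mask & (tmap > t_high)] = "H"
    labels[mask & (tmap < t_low)] = "V"
    return ClusterAssignment(labels=labels, t_high=t_high, t_low=t_low, pct=pct, roi=roi)


def assignment_from_thresholds(tmap, roi_mask, t_high, t_low, pct=95.0, roi="") -> ClusterAssignment:
    """Reproduce an assignment from stored thresholds (determinism guarantee)."""
    tmap = np.asarray(tmap, dtype=float)
    mask = np.ones(len(tmap), bool) if roi_mask is None else np.asarray(roi_mask, bool)
    labels = np.full(len(tmap), "none", dtype=object)
    labels[mask & (tmap > t_high)] = "H"
    labels[mask & (tmap < t_low)] = "V"
    return ClusterAssignment(labels=labels, t_high=t_high, t_low=t_low, pct=pct, roi=roi)


#: preferred condition of each cluster
PREFERRED = {"H": "horizontal", "V": "vertical"}


def summarize_cluster_psc(
    assignment: ClusterAssignment,
    betas: Mapping[tuple[str, str], np.ndarray],
) -> dict[tuple[str, str], float]:
    """Mean preferred-condition PSC per cluster and condition type.

    ``betas`` maps ``(condition_type, condition)`` — e.g. ``('physical',
    'horizontal')`` — to per-voxel PSC beta estimates.  Returns
    ``{(cluster, condition_type): mean}``; empty clusters yield NaN (flagged
    missing cell) rather than an exception.
    """
    condition_types = sorted({ct for ct, _ in betas})
    out: dict[tuple[str, str], float] = {}
    for cluster, cond in PREFERRED.items():
        idx = assignment.members(cluster)
        for ct in condition_types:
            if (ct, cond) not in betas:
                continue
            if len(idx) == 0:
                out[(cluster, ct)] = float("nan")
            else:
                out[(cluster, ct)] = float(np.mean(np.asarray(betas[(ct, cond)])[idx]))
    return out


def compare_conditions(
    summary: pd.DataFrame,
    value: str = "mean_psc",
    between: tuple[str, str] = ("physical", "ambiguous"),
    mode: str = "auto",
) -> GroupComparison:
    """Paired Wilcoxon signed-rank test of physical vs ambiguous cluster PSC.

    ``summary`` holds one row per (subject, hemisphere, condition_type) cell;
    rows are paired on (subject, hemisphere).  Exact two-sided p for small N
    (<= 25), normal approximation above; both are reported.
    """
    wide = summary.pivot_table(index=["subject", "hemisphere"], columns="condition_type", values=value)
    wide = wide.dropna(subset=list(between))
    if len(wide) == 0:
        raise MissingDataError("no complete physical/ambiguous pairs to compare")
    try:
        return wilcoxon_signed_rank(wide[between[0]].to_numpy(), wide[between[1]].to_numpy(), mode=mode)
    except UndefinedTestError:
        raise


def apply_subject_qc(motion_max_mm: Mapping[str, float] | np.ndarray, voxel_size_mm: float = 0.8) -> bool:
    """Head-motion inclusion rule: exclude a subject when any run's maximum
    absolute motion exceeds twice the voxel size (strictly; exactly 2x is
    still included).  Returns True when the subject is retained."""
    if isinstance(motion_max_mm, Mapping):
        values = np.asarray(list(motion_max_mm.values()), dtype=float)
    else:
        values = np.asarray(motion_max_mm, dtype=float)
    if values.size == 0 or np.isnan(values).any():
        raise MissingDataError("missing motion record")
    return bool((values <= 2.0 * voxel_size_mm).all())
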