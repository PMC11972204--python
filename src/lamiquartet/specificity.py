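"""Condition specificity: how selective a voxel is for its winning condition.

Winner-take-all labels say which condition won, not by how much.  The
specificity score complements them: each voxel's (beta_H, beta_V) pair is
compared, after clamping negative components to zero, against the maximally
selective reference vector (the winner's axis) via cosine similarity, then
rescaled so that an equal-response voxel (45 degrees) scores 0 and a
pure-preference voxel scores 1.  The score is invariant to positive scaling
of the beta pair.

The formula lives in a single function so an alternative definition (for
example allowing obtuse angles with truncation at zero) can be swapped in
without touching callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lamiquartet.clusters import ClusterAssignment
from lamiquartet.stats import sem

_COS45 = np.sqrt(0.5)


def voxel_specificity(
    beta_h: np.ndarray | float,
    beta_v: np.ndarray | float,
    clamp_negative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Specificity s in [0, 1] and winner label per voxel.

    With ``clamp_negative`` (default) negative betas are clamped to 0 before
    the cosine, which confines s to [0, 1]; otherwise obtuse angles yield
    negative raw scores that are truncated at 0.  Voxels whose betas are both
    <= 0 are undefined and flagged NaN.
    """
    bh = np.atleast_1d(np.asarray(beta_h, dtype=float))
    bv = np.atleast_1d(np.asarray(beta_v, dtype=float))
    if bh.shape != bv.shape:
        raise ValueError("beta_h and beta_v must have the same shape")
    undefined = (bh <= 0) & (bv <= 0)
    winner = np.where(bh >= bv, "H", "V").astype(object)
    winner[undefined] = "none"
    if clamp_negative:
        bh, bv = np.maximum(bh, 0.0), np.maximum(bv, 0.0)
    norm = np.sqrt(bh**2 + bv**2)
    norm = np.where(norm == 0, 1.0, norm)
    b_win = np.where(bh >= bv, bh, bv)
    cos = b_win / norm
    s = (cos - _COS45) / (1.0 - _COS45)
    if not clamp_negative:
        s = np.maximum(s, 0.0)
    s = np.clip(s, 0.0, 1.0)
    s[undefined] = np.nan
    return s, winner


def cluster_specificity(
    s: np.ndarray,
    assignment: ClusterAssignment,
) -> dict[str, tuple[float, float, int]]:
    """Mean +/- SEM specificity over each cluster's member voxels.

    Returns ``{cluster: (mean, sem, n)}``; empty clusters (or clusters with
    only undefined voxels) give a NaN mean with n = 0 (missing cell).
    """
    out: dict[str, tuple[float, float, int]] = {}
    for cluster in ("H", "V"):
        vals = np.asarray(s, dtype=float)[assignment.members(cluster)]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            out[cluster] = (float("nan"), float("nan"), 0)
        else:
            out[cluster] = (float(vals.mean()), sem(vals), len(vals))
    return out


def group_specificity(per_subject: pd.DataFrame, value: str = "specificity") -> tuple[float, float, int]:
    """Group mean +/- SEM of per-subject specificity values."""
    vals = per_subject[value].dropna().to_numpy()
    return float(vals.mean()), sem(vals), len(vals)
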