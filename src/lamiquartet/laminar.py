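"""Laminar analysis: layer binning, columnar cluster extension, differential
profiles and slope tests.

Voxels are binned into three equivolume layers (deep, middle, superficial —
equal tertiles of the depth coordinate).  Because winner-take-all thresholds
select voxels sparsely along the depth axis, cluster labels are first extended
through the cortical thickness: a column inherits a label when any assigned
voxel lies within a tangential radius (0.39 in parametrized (u, v) units) of
its center — a disk approximation of the moving cylinder whose height is the
local thickness.

Differential laminar profiles (physical - ambiguous) cancel the macrovascular
draining-vein component that is shared between conditions, under the
assumption that the macrovascular weight adds linearly to the microvascular
one; the per-subject slope of the differential profile (averaged across the
two clusters) is tested against zero with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lamiquartet.clusters import ClusterAssignment
from lamiquartet.stats import GroupComparison, sem, wilcoxon_signed_rank
from lamiquartet.synth import CorticalPatch

LAYERS = ("deep", "middle", "superficial")


class LayerError(ValueError):
    """A required depth layer is empty or the layers mismatch."""


@dataclass(frozen=True)
class DepthBins:
    """Edges on equivolume depth partitioning [0, 1] into named layers."""

    edges: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise LayerError("edges must increase from 0 to 1")
        if len(e) != 4:
            raise LayerError("exactly three layers (four edges) are supported")

    def layer_index(self, d: np.ndarray) -> np.ndarray:
        """0 = deep, 1 = middle, 2 = superficial; d = 1 maps to superficial."""
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges)[1:-1], d, side="right")
        return idx

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0


def extend_clusters_columnwise(
    assignment: ClusterAssignment,
    patch: CorticalPatch,
    radius: float = 0.39,
) -> ClusterAssignment:
    """Propagate cluster labels through the cortical depth of nearby columns.

    A column inherits a label when any assigned voxel lies within tangential
    ``radius`` of its (u, v) center; the whole depth of the column is then
    labeled.  When both H and V voxels fall within the radius the nearest
    assigned voxel wins; among exactly equidistant voxels (e.g. several
    assigned voxels in the same column) the majority label wins, with any
    remaining tie resolved by lowest voxel index — all deterministic.
    ``radius = 0`` labels only columns that already contain assigned voxels.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = np.asarray(assignment.labels, dtype=object)
    assigned = np.flatnonzero(labels != "none")
    new = np.full(patch.n_voxels, "none", dtype=object)
    if len(assigned) == 0:
        return ClusterAssignment(new, assignment.t_high, assignment.t_low, assignment.pct, assignment.roi)
    au, av, alab = patch.u[assigned], patch.v[assigned], labels[assigned]
    for cid in patch.column_ids():
        m = patch.column_id == cid
        cu, cv = patch.u[m][0], patch.v[m][0]
        dist = np.hypot(au - cu, av - cv)
        close = dist <= radius + 1e-12
        if not close.any():
            continue
        dmin = dist[close].min()
        at_min = np.flatnonzero(close & (dist <= dmin + 1e-12))
        labs = alab[at_min]
        n_h, n_v = int(np.sum(labs == "H")), int(np.sum(labs == "V"))
        if n_h != n_v:
            new[m] = "H" if n_h > n_v else "V"
        else:
            new[m] = labs[0]  # lowest voxel index
    return ClusterAssignment(new, assignment.t_high, assignment.t_low, assignment.pct, assignment.roi)


@dataclass
class LaminarProfile:
    """Layer-wise mean PSC (+SEM, voxel counts) for one cluster x condition."""

    mean: np.ndarray  # 3 layers
    sem: np.ndarray
    n: np.ndarray
    layers: tuple[str, ...] = LAYERS
    centers: np.ndarray = field(default_factory=lambda: DepthBins().centers)


def laminar_profile(
    betas: np.ndarray,
    assignment: ClusterAssignment,
    d_ev: np.ndarray,
    cluster: str,
    bins: DepthBins = DepthBins(),
) -> LaminarProfile:
    """Layer means of PSC betas over one (extended) cluster's voxels.

    Raises :class:`LayerError` if any of the three layers has no member voxel.
    """
    idx = assignment.members(cluster)
    if len(idx) == 0:
        raise LayerError(f"cluster {cluster!r} is empty")
    b = np.asarray(betas, dtype=float)[idx]
    layer = bins.layer_index(np.asarray(d_ev)[idx])
    mean = np.empty(3)
    sems = np.empty(3)
    counts = np.empty(3, dtype=int)
    for k in range(3):
        vals = b[layer == k]
        if len(vals) == 0:
            raise LayerError(f"layer {LAYERS[k]!r} empty for cluster {cluster!r}")
        mean[k], sems[k], counts[k] = vals.mean(), sem(vals), len(vals)
    return LaminarProfile(mean=mean, sem=sems, n=counts, centers=bins.centers)


def differential_profile(phys: LaminarProfile, amb: LaminarProfile) -> LaminarProfile:
    """Physical minus ambiguous per layer, with propagated SEM."""
    if phys.layers != amb.layers or len(phys.mean) != len(amb.mean):
        raise LayerError("layer mismatch between profiles")
    return LaminarProfile(
        mean=phys.mean - amb.mean,
        sem=np.sqrt(phys.sem**2 + amb.sem**2),
        n=np.minimum(phys.n, amb.n),
        layers=phys.layers,
        centers=phys.centers,
    )


def profile_slope(values: np.ndarray, centers: np.ndarray | None = None) -> float:
    """OLS slope of layer values against layer-center depth.

    With the default tertile centers (1/6, 1/2, 5/6) the slope is in PSC per
    unit cortical depth; three-point OLS is exact for affine profiles.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise LayerError("need at least three layers for a slope")
    x = DepthBins().centers if centers is None else np.asarray(centers, dtype=float)
    return float(np.polyfit(x, values, 1)[0])


@dataclass(frozen=True)
class SlopeStat:
    slopes: np.ndarray  # one per subject
    comparison: GroupComparison | None  # None when the test is undefined


def slope_test(slopes_per_subject: np.ndarray, mode: str = "auto") -> SlopeStat:
    """Two-sided Wilcoxon signed-rank test of per-subject differential slopes
    against zero.  All-zero slopes leave the test undefined (reported as
    ``comparison=None``)."""
    slopes = np.asarray(slopes_per_subject, dtype=float)
    slopes = slopes[~np.isnan(slopes)]
    if np.all(slopes == 0):
        return SlopeStat(slopes=slopes, comparison=None)
    return SlopeStat(slopes=slopes, comparison=wilcoxon_signed_rank(slopes, mode=mode))
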