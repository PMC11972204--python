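"""Event-related averages (ERA) of cluster time courses.

Cluster time courses (voxel-pooled averages per run) are cut into trials at
condition onsets, converted to percent signal change relative to the
onset-volume value — ``psc = (x - x0) / x0 * 100`` — and aligned at offset 0.
Ambiguous (percept-driven) trials shorter than 10 s (5 TR at TR 2 s) are
excluded, and surviving trials are truncated to the analysis window so every
time point averages the same number of trials (balanced average).  Temporal
similarity between curves is quantified per subject by Spearman correlation
and tested at the group level with the Wilcoxon signed-rank test.

Onsets snap to the nearest earlier volume; there is no temporal
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from lamiquartet.stats import GroupComparison, wilcoxon_signed_rank


class TrialError(ValueError):
    """Trial extraction or selection cannot proceed."""


@dataclass
class TrialSet:
    """Trials x time points PSC with per-trial metadata."""

    values: np.ndarray  # n_trials x (window_tr + 1)
    condition: np.ndarray  # per-trial trial_type
    duration_s: np.ndarray
    valid: np.ndarray  # False where the onset value was 0 (PSC undefined)
    window_tr: int

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, mask: np.ndarray) -> "TrialSet":
        return TrialSet(
            self.values[mask], self.condition[mask], self.duration_s[mask], self.valid[mask], self.window_tr
        )


def extract_trials(
    timecourse: np.ndarray,
    events: pd.DataFrame,
    tr_s: float,
    window_tr: int = 5,
    conditions: tuple[str, ...] = ("horizontal", "vertical"),
    source: str | None = None,
) -> TrialSet:
    """Cut a cluster time course into onset-aligned PSC trials.

    Each retained trial spans offsets 0..``window_tr`` volumes from the onset
    volume; trials whose window would run past the end of the run are dropped.
    Trials with a zero onset value are flagged invalid.
    """
    x = np.asarray(timecourse, dtype=float)
    n = len(x)
    mask = events["trial_type"].isin(conditions).to_numpy()
    if source is not None:
        mask &= (events["source"] == source).to_numpy()
    onsets = events["onset"].to_numpy()[mask]
    durations = events["duration"].to_numpy()[mask]
    types = events["trial_type"].to_numpy()[mask]
    rows, conds, durs, valid = [], [], [], []
    for onset, duration, ttype in zip(onsets, durations, types):
        if onset < 0 or onset >= n * tr_s:
            raise TrialError(f"onset {onset} outside the run")
        i0 = int(np.floor(onset / tr_s + 1e-9))  # nearest earlier volume
        if i0 + window_tr >= n:
            continue  # window would exceed the run
        seg = x[i0 : i0 + window_tr + 1]
        x0 = seg[0]
        if x0 == 0:
            rows.append(np.full(window_tr + 1, np.nan))
            valid.append(False)
        else:
            rows.append((seg - x0) / x0 * 100.0)
            valid.append(True)
        conds.append(ttype)
        durs.append(duration)
    return TrialSet(
        values=np.array(rows).reshape(-1, window_tr + 1),
        condition=np.array(conds, dtype=object),
        duration_s=np.array(durs, dtype=float),
        valid=np.array(valid, dtype=bool),
        window_tr=window_tr,
    )


def select_trials(trials: TrialSet, min_duration_s: float = 10.0) -> TrialSet:
    """Keep valid trials of at least ``min_duration_s`` (default 10 s = 5 TR).

    Survivors are already truncated to the analysis window by extraction, so
    every retained trial contributes the same number of samples.  Raises
    :class:`TrialError` when no trial survives.
    """
    keep = trials.valid & (trials.duration_s >= min_duration_s - 1e-9)
    if not keep.any():
        raise TrialError("no trials survive the duration threshold")
    return trials.subset(keep)


@dataclass
class ERACurve:
    """Mean PSC +/- SEM per TR offset, with the (equal) trial count."""

    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    tr_s: float = 2.0
    offsets: np.ndarray = field(default_factory=lambda: np.arange(6))


def average_trials(trials: TrialSet, tr_s: float = 2.0) -> ERACurve:
    if len(trials) == 0:
        raise TrialError("cannot average an empty trial set")
    vals = trials.values
    n = len(vals)
    sem = vals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(vals.shape[1])
    return ERACurve(mean=vals.mean(axis=0), sem=sem, n_trials=n, tr_s=tr_s, offsets=np.arange(vals.shape[1]))


def pool_roles_and_average(
    trials_by_cluster: dict[str, TrialSet],
    tr_s: float = 2.0,
) -> dict[str, ERACurve]:
    """Pool the two clusters into preferred / not-preferred role averages.

    ``preferred`` pools the H cluster's horizontal trials with the V cluster's
    vertical trials; ``not_preferred`` the crossed pairs.  Raises
    :class:`TrialError` when a role has no trials.
    """
    for cl in ("H", "V"):
        if cl not in trials_by_cluster:
            raise TrialError(f"missing trials for cluster {cl!r}")
    pref_map = {"preferred": {"H": "horizontal", "V": "vertical"}, "not_preferred": {"H": "vertical", "V": "horizontal"}}
    out: dict[str, ERACurve] = {}
    for role, mapping in pref_map.items():
        parts = []
        for cl, cond in mapping.items():
            ts = trials_by_cluster[cl]
            parts.append(ts.values[ts.valid & (ts.condition == cond)])
        pooled = np.concatenate(parts, axis=0)
        if len(pooled) == 0:
            raise TrialError(f"no trials for role {role!r}")
        n = len(pooled)
        sem = pooled.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(pooled.shape[1])
        out[role] = ERACurve(mean=pooled.mean(axis=0), sem=sem, n_trials=n, tr_s=tr_s, offsets=np.arange(pooled.shape[1]))
    return out


@dataclass(frozen=True)
class SimilarityStat:
    rhos: np.ndarray  # one Spearman rho per subject
    comparison: GroupComparison | None
    n_dropped: int = 0


def similarity_test(
    curves_a: list[np.ndarray],
    curves_b: list[np.ndarray],
    mode: str = "auto",
) -> SimilarityStat:
    """Spearman rho per subject between two paired curves, then a two-sided
    Wilcoxon signed-rank test of the rhos against zero.

    Constant curves leave rho undefined; those subjects are dropped with a
    warning.  Average ranks handle exact ties.  The same machinery serves the
    within-area preferred/not-preferred comparison and the cross-area
    comparison of role-averaged curves.
    """
    if len(curves_a) != len(curves_b):
        raise ValueError("need one curve pair per subject")
    rhos = []
    dropped = 0
    for a, b in zip(curves_a, curves_b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.shape != b.shape:
            raise ValueError("paired curves must share offsets")
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            dropped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = sps.spearmanr(a, b).statistic
        rhos.append(float(rho))
    if dropped:
        warnings.warn(f"dropped {dropped} subject(s) with constant curves", RuntimeWarning)
    rhos_arr = np.array(rhos)
    if len(rhos_arr) == 0 or np.all(rhos_arr == 0):
        return SimilarityStat(rhos=rhos_arr, comparison=None, n_dropped=dropped)
    return SimilarityStat(rhos=rhos_arr, comparison=wilcoxon_signed_rank(rhos_arr, mode=mode), n_dropped=dropped)
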