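"""Rank-based group statistics shared by the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class UndefinedTestError(ValueError):
    """The test statistic is undefined for the given data (e.g. all-zero differences)."""


@dataclass(frozen=True)
class GroupComparison:
    """Result of a paired (or one-sample) group-level test."""

    n: int
    statistic: float
    p_value: float
    test: str
    p_exact: float | None = None
    p_approx: float | None = None


def _exact_signed_rank_enum(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by full enumeration of all 2^n sign
    assignments.  Uses midranks, so it stays exact in the presence of tied
    absolute differences (where the tabulated null distribution does not
    apply).  Returns (W+, p)."""
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # all subsets
    w_all = signs @ ranks
    p = float(np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12))
    return w_obs, p


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    mode: str = "auto",
    exact_max_n: int = 25,
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired values (or one sample vs 0).

    ``mode='auto'`` uses the exact null distribution for n <= ``exact_max_n``
    (full 2^n enumeration, midranks when absolute differences tie) and the
    normal approximation above; ``'exact'`` / ``'approx'`` force a method.
    Both p-values are reported alongside the selected one.  Zero differences
    are dropped (Wilcoxon's original rule); all-zero differences leave the
    test undefined.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    d_nz = d[d != 0]
    if len(d_nz) == 0:
        raise UndefinedTestError("all paired differences are zero; signed-rank test undefined")
    has_ties = len(np.unique(np.abs(d_nz))) < len(d_nz)
    p_exact = None
    if len(d_nz) <= exact_max_n:
        if has_ties:
            stat, p_exact = _exact_signed_rank_enum(d_nz)
        else:
            res = sps.wilcoxon(d_nz, method="exact", alternative="two-sided")
            p_exact = float(res.pvalue)
            stat = float(res.statistic)
    res_a = sps.wilcoxon(d_nz, method="approx", alternative="two-sided", correction=True)
    p_approx = float(res_a.pvalue)
    if p_exact is None:
        stat = float(res_a.statistic)
    if mode == "exact":
        if p_exact is None:
            raise UndefinedTestError("exact test unavailable (ties or n too large)")
        p = p_exact
    elif mode == "approx":
        p = p_approx
    elif mode == "auto":
        p = p_exact if p_exact is not None else p_approx
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(
        n=len(d),
        statistic=stat,
        p_value=p,
        test="wilcoxon-signed-rank",
        p_exact=p_exact,
        p_approx=p_approx,
    )


def sem(values: np.ndarray) -> float:
    """Standard error of the mean (ddof=1; 0 for a single value)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))
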