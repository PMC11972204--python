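"""Percent-signal-change GLM analysis of quartet runs.

Implements the univariate analysis chain: time-course normalization to
percent of the temporal mean, discrete-cosine high-pass (as confound columns
by default so degree-of-freedom bookkeeping stays explicit), canonical
double-gamma HRF convolution of condition boxcars, ordinary-least-squares
fitting with AR(2) serial-correlation correction (two-iteration
Cochrane–Orcutt with Yule–Walker estimation), and the balanced
horizontal-greater-than-vertical contrast.

Because the data are normalized to a temporal mean of 100, a boxcar regressor
with unit plateau makes the fitted beta directly interpretable as percent
signal change relative to the unmodeled baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from lamiquartet.events import validate_events

#: Task conditions modeled by default (three predictors).
TASK_CONDITIONS = ("horizontal", "vertical", "flicker")

#: Finite sentinel returned for t statistics with (numerically) zero residual.
T_SENTINEL = 1e6


class DesignError(ValueError):
    """Design matrix cannot be built or is rank deficient."""


class FitError(ValueError):
    """GLM cannot be fit (singular design, insufficient data)."""


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: response peak at ~6 s, undershoot at ~16 s,
    peak-to-undershoot amplitude ratio 6:1, length 32 s."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - special.gammaln(shape) - shape * np.log(scale)
    )
    return out


def double_gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the double-gamma HRF at times ``t`` (s); peak normalized to 1.

    Gamma shapes are chosen so each component's mode sits at its stated delay
    (shape = delay/dispersion + 1).
    """
    t = np.asarray(t, dtype=float)
    p = params
    h = _gamma_pdf(t, p.peak_delay_s / p.peak_disp_s + 1.0, p.peak_disp_s) - (
        _gamma_pdf(t, p.undershoot_delay_s / p.undershoot_disp_s + 1.0, p.undershoot_disp_s) / p.ratio
    )
    peak = h.max()
    return h / peak if peak > 0 else h


# ---------------------------------------------------------------------------
# Normalization / high-pass
# ---------------------------------------------------------------------------


def normalize_psc(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize each voxel time course to percent of its temporal mean.

    ``y_norm = y / y_mean * 100``.  Returns ``(normalized, valid)`` where
    ``valid`` flags voxels with non-zero temporal mean; invalid voxels are
    filled with NaN rather than silently propagated.
    """
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=0)
    valid = np.abs(mean) > 1e-12
    out = np.full_like(data, np.nan)
    out[:, valid] = data[:, valid] / mean[valid] * 100.0
    return out, valid


def dct_basis(n_volumes: int, n_functions: int) -> np.ndarray:
    """Unit-norm DCT-II basis columns k = 1..n_functions (constant excluded)."""
    t = np.arange(n_volumes)
    ks = np.arange(1, n_functions + 1)
    basis = np.cos(np.pi * np.outer(2 * t + 1, ks) / (2 * n_volumes))
    return basis / np.linalg.norm(basis, axis=0)


def n_dct_for_cutoff(n_volumes: int, tr_s: float, cycles_per_run: float) -> int:
    """Number of DCT columns with frequency at or below ``cycles_per_run``
    cycles per run.  Column k has frequency k / (2 * T); the cutoff is
    cycles / T, hence k <= 2 * cycles."""
    if cycles_per_run < 1:
        raise DesignError("cycles_per_run must be >= 1")
    run_s = n_volumes * tr_s
    if cycles_per_run / run_s > 0.5 / tr_s:
        raise DesignError("high-pass cutoff above Nyquist frequency")
    return int(np.floor(2 * cycles_per_run + 1e-9))


def highpass(
    data: np.ndarray, tr_s: float, cycles_per_run: float = 5.0, mode: str = "filter"
) -> np.ndarray:
    """High-pass by projecting out slow DCT components up to
    ``cycles_per_run`` cycles per run (5 cycles by default, matching quartet
    runs).  ``mode='filter'`` returns the residual series; ``mode='confound'``
    returns the confound columns to include in a design matrix instead."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    basis = dct_basis(n, n_dct_for_cutoff(n, tr_s, cycles_per_run))
    if mode == "confound":
        return basis
    if mode != "filter":
        raise ValueError(f"unknown mode {mode!r}")
    return data - basis @ (basis.T @ data)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Task regressors + confounds + intercept, with provenance labels."""

    task: np.ndarray
    task_names: tuple[str, ...]
    confounds: np.ndarray
    confound_names: tuple[str, ...]
    tr_s: float
    rank_deficient_tasks: tuple[str, ...] = field(default_factory=tuple)

    @property
    def matrix(self) -> np.ndarray:
        n = self.task.shape[0]
        return np.column_stack([self.task, self.confounds, np.ones(n)])

    @property
    def names(self) -> tuple[str, ...]:
        return self.task_names + self.confound_names + ("intercept",)

    @property
    def n_volumes(self) -> int:
        return self.task.shape[0]

    def full_rank(self) -> bool:
        m = self.matrix
        return np.linalg.matrix_rank(m) == m.shape[1]


_regressor_cache: dict = {}


def condition_regressors(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    conditions: tuple[str, ...],
    hrf: HRFParams = HRFParams(),
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressors sampled at volume times.

    Boxcars are built on a fine grid (``dt`` s) so percept onsets that fall
    between volumes are represented accurately, convolved with the canonical
    HRF, then sampled at t = volume_index * TR.  Results are memoized on the
    event rows and sampling parameters (schedules repeat across runs).
    """
    key = (
        tuple(map(tuple, events[["onset", "duration", "trial_type"]].itertuples(index=False))),
        n_volumes,
        tr_s,
        conditions,
        hrf,
        dt,
    )
    cached = _regressor_cache.get(key)
    if cached is not None:
        return cached.copy()
    validate_events(events)
    run_s = n_volumes * tr_s
    ends = events["onset"] + events["duration"]
    if (events["onset"] < -1e-9).any() or (ends > run_s + tr_s + 1e-9).any():
        raise DesignError("events exceed run length")
    n_fine = int(np.ceil(run_s / dt)) + 1
    kernel = double_gamma_hrf(np.arange(0, hrf.length_s + dt, dt), hrf)
    kernel = kernel / kernel.sum()  # unit steady-state gain: sustained boxcar -> plateau 1
    out = np.zeros((n_volumes, len(conditions)))
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    for j, cond in enumerate(conditions):
        sel = events.loc[events["trial_type"] == cond]
        box = np.zeros(n_fine)
        for row in sel.itertuples():
            i0 = int(np.round(row.onset / dt))
            i1 = min(int(np.round((row.onset + row.duration) / dt)), n_fine)
            box[i0:i1] = 1.0
        out[:, j] = np.convolve(box, kernel)[:n_fine][vol_idx]
    if len(_regressor_cache) > 64:
        _regressor_cache.clear()
    _regressor_cache[key] = out
    return out.copy()


def build_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    hrf: HRFParams = HRFParams(),
    conditions: tuple[str, ...] = TASK_CONDITIONS,
    source: str | None = None,
    highpass_cycles: float | None = 5.0,
    dt: float = 0.1,
) -> DesignMatrix:
    """Build the run design matrix.

    One HRF-convolved column per condition (three predictors — horizontal,
    vertical, flicker — by default).  For physical runs the motion columns are
    time-locked to stimulus events; for ambiguous runs pass the percept-source
    events so they are time-locked to the subject's perceptual reports.
    ``source`` restricts the motion conditions to one event source while
    flicker is always taken from the stimulus stream.
    """
    unknown = set(events["trial_type"]) - {"fixation", *conditions, "ambiguous"}
    if unknown:
        raise DesignError(f"unknown condition labels {sorted(unknown)}")
    if source is not None:
        motion = events.loc[
            (events["source"] == source) & events["trial_type"].isin(("horizontal", "vertical"))
        ]
        other = events.loc[
            (events["source"] == "stimulus")
            & events["trial_type"].isin([c for c in conditions if c not in ("horizontal", "vertical")])
        ]
        events = pd.concat([motion, other]).sort_values("onset").reset_index(drop=True)
    task = condition_regressors(events, n_volumes, tr_s, conditions, hrf, dt)
    empty = tuple(c for j, c in enumerate(conditions) if not np.any(task[:, j]))
    if highpass_cycles is not None:
        conf = dct_basis(n_volumes, n_dct_for_cutoff(n_volumes, tr_s, highpass_cycles))
        conf_names = tuple(f"dct{k}" for k in range(1, conf.shape[1] + 1))
    else:
        conf = np.empty((n_volumes, 0))
        conf_names = ()
    return DesignMatrix(task, tuple(conditions), conf, conf_names, tr_s, rank_deficient_tasks=empty)


# ---------------------------------------------------------------------------
# AR(2)-corrected GLM
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    betas: np.ndarray  # regressors x voxels
    names: tuple[str, ...]
    residual_sd: np.ndarray  # voxels
    ar_coefs: np.ndarray  # ar_order x voxels
    df: int
    design: DesignMatrix
    _xtx_inv: np.ndarray | None = None  # voxels x p x p (whitened)

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def _yule_walker(resid: np.ndarray, order: int) -> np.ndarray:
    """Per-voxel Yule–Walker AR coefficients from residuals (volumes x voxels)."""
    n, v = resid.shape
    r = resid - resid.mean(axis=0)
    denom = np.einsum("tv,tv->v", r, r)
    denom = np.where(denom < 1e-300, 1.0, denom)
    acf = np.empty((order, v))
    for k in range(1, order + 1):
        acf[k - 1] = np.einsum("tv,tv->v", r[k:], r[:-k]) / denom
    if order == 1:
        return acf
    if order == 2:
        r1, r2 = acf
        det = 1.0 - r1**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        a1 = r1 * (1.0 - r2) / det
        a2 = (r2 - r1**2) / det
        coefs = np.vstack([a1, a2])
    else:  # pragma: no cover - orders above 2 unused by the pipeline
        coefs = np.empty((order, v))
        for j in range(v):
            rr = np.concatenate([[1.0], acf[:, j]])
            toep = np.array([[rr[abs(i - k)] for k in range(order)] for i in range(order)])
            coefs[:, j] = np.linalg.solve(toep, acf[:, j])
    # keep inside the stationarity region
    return np.clip(coefs, -0.98, 0.98)


def _whiten(x: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Apply the AR inverse filter y_t - sum_k a_k y_{t-k}; drops first
    ``order`` samples.  ``x``: volumes x cols; ``coefs``: order vector."""
    order = len(coefs)
    out = x[order:].copy()
    for k, a in enumerate(coefs, start=1):
        out -= a * x[order - k : -k if k else None]
    return out


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    ar_order: int = 2,
    n_iter: int = 2,
) -> GLMResult:
    """Fit the GLM with AR serial-correlation correction.

    OLS first; AR(``ar_order``) coefficients are then estimated per voxel from
    the residuals by Yule–Walker, data and design are prewhitened and refit
    (``n_iter`` Cochrane–Orcutt iterations).  Voxels with numerically zero
    residual variance (e.g. noiseless simulations) skip whitening.
    """
    data = np.asarray(data, dtype=float)
    X = design.matrix
    n, p = X.shape
    if data.shape[0] != n:
        raise FitError(f"data has {data.shape[0]} volumes, design {n}")
    if n <= p + ar_order:
        raise FitError("fewer volumes than regressors")
    if not design.full_rank():
        cond = np.linalg.cond(X)
        raise FitError(
            f"rank-deficient design (cond={cond:.3g}; empty task columns: "
            f"{design.rank_deficient_tasks})"
        )
    v = data.shape[1]
    betas, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ betas
    resid_var = (resid**2).sum(axis=0) / max(n - p, 1)
    noiseless = resid_var < 1e-20
    ar = np.zeros((ar_order, v))
    df = n - ar_order - p
    for _ in range(n_iter):
        est = _yule_walker(resid, ar_order)
        ar = np.where(noiseless[None, :], 0.0, est)
        # whitened refit against the ORIGINAL data each iteration, batched
        # over voxels: Xw[v] = X[t] - sum_k a_k[v] X[t-k]
        Xw = np.broadcast_to(X[ar_order:], (v, n - ar_order, p)).copy()
        yw = data[ar_order:].T.copy()
        for k in range(1, ar_order + 1):
            lag = slice(ar_order - k, -k)
            Xw -= ar[k - 1][:, None, None] * X[lag]
            yw -= ar[k - 1][:, None] * data[lag].T
        XwT = Xw.transpose(0, 2, 1)
        gram = XwT @ Xw
        xty = (XwT @ yw[:, :, None])[:, :, 0]
        try:
            xtx_inv = np.linalg.inv(gram)
        except np.linalg.LinAlgError:  # near-singular whitened design
            raise FitError(f"near-singular whitened design (cond={np.linalg.cond(gram).max():.3g}")
        betas = (xtx_inv @ xty[:, :, None])[:, :, 0].T
        rw = yw - (Xw @ betas.T[:, :, None])[:, :, 0]
        sigma2 = (rw**2).sum(axis=1) / max(df, 1)
        resid = data - X @ betas
    return GLMResult(
        betas=betas,
        names=design.names,
        residual_sd=np.sqrt(sigma2),
        ar_coefs=ar,
        df=df,
        design=design,
        _xtx_inv=xtx_inv,
    )


def contrast_t(result: GLMResult, contrast: str = "H>V") -> np.ndarray:
    """t statistic per voxel for a two-condition contrast.

    ``"H>V"`` tests beta_horizontal - beta_vertical; ``"V>H"`` the negation.
    Voxels with zero residual variance return a capped sentinel (sign of the
    contrast times ``T_SENTINEL``) with a warning.
    """
    pair = {"H>V": ("horizontal", "vertical"), "V>H": ("vertical", "horizontal")}
    if contrast not in pair:
        raise ValueError(f"unknown contrast {contrast!r}")
    a, b = pair[contrast]
    for cond in (a, b):
        if cond not in result.names:
            raise FitError(f"condition {cond!r} absent from the design")
        if cond in result.design.rank_deficient_tasks:
            raise FitError(f"condition {cond!r} has an empty (flat) design column")
    c = np.zeros(len(result.names))
    c[result.names.index(a)] = 1.0
    c[result.names.index(b)] = -1.0
    diff = c @ result.betas
    var_c = ((result._xtx_inv @ c) @ c) * result.residual_sd**2
    t = np.empty_like(diff)
    zero = var_c < 1e-24
    if zero.any():
        warnings.warn("zero-residual voxels: t capped at finite sentinel", RuntimeWarning)
        t[zero] = np.sign(diff[zero]) * T_SENTINEL
    t[~zero] = diff[~zero] / np.sqrt(var_c[~zero])
    return t


# ---------------------------------------------------------------------------
# Balanced contrast (ambiguous runs)
# ---------------------------------------------------------------------------


def balance_events(
    events: pd.DataFrame,
    tr_s: float,
    seed: int | np.random.Generator = 0,
    conditions: tuple[str, str] = ("horizontal", "vertical"),
) -> pd.DataFrame:
    """Equalize total time of two conditions by dropping whole events.

    Drops whole events from the over-represented condition, largest first
    among events that do not overshoot the tolerance (duration <= excess +
    one TR), until the condition totals match within one TR; when every
    remaining event would overshoot, the smallest is dropped so the residual
    imbalance stays minimal.  Ties among equal durations are broken by a
    seeded shuffle.  Used so the H>V contrast of percept-driven runs compares
    an equal number of time points per condition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev = events.reset_index(drop=True)
    totals = {c: ev.loc[ev["trial_type"] == c, "duration"].sum() for c in conditions}
    longer = max(conditions, key=lambda c: totals[c])
    shorter = min(conditions, key=lambda c: totals[c])
    excess = totals[longer] - totals[shorter]
    cand = ev.index[ev["trial_type"] == longer].to_numpy()
    cand = cand[rng.permutation(len(cand))]  # seeded tie-break
    cand = list(cand[np.argsort(-ev.loc[cand, "duration"].to_numpy(), kind="stable")])
    drop = []
    while excess > tr_s and cand:
        admissible = [i for i in cand if ev.loc[i, "duration"] <= excess + tr_s]
        i = admissible[0] if admissible else cand[-1]  # largest admissible, else smallest
        cand.remove(i)
        drop.append(i)
        excess -= ev.loc[i, "duration"]
    return ev.drop(index=drop).reset_index(drop=True)


def balanced_contrast_t(
    data: np.ndarray,
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    contrast: str = "H>V",
    source: str | None = None,
    seed: int | np.random.Generator = 0,
    **design_kwargs,
) -> np.ndarray:
    """Contrast t after balancing condition time: events of the longer motion
    condition are subsampled (whole events, largest-first, seeded) to match
    total time points before the design is rebuilt and the model refit."""
    balanced = balance_events(events, tr_s, seed)
    design = build_design(balanced, n_volumes, tr_s, source=source, **design_kwargs)
    result = fit_glm(data, design)
    return contrast_t(result, contrast)
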