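"""Ground-truthed synthetic cortical patches and laminar BOLD time series.

The generator emulates the measurement situation of a submillimeter BOLD
experiment on two regions of interest — a retinotopic V1-like patch and an
hMT+-like columnar patch — each organized into interleaved columns preferring
horizontal or vertical motion.  Every voxel carries tangential coordinates
(u, v), an equivolume cortical depth d in [0, 1] (0 = white-matter side) and a
ground-truth cluster label.

The signal model is linear in percent signal change (PSC):

    psc_c(voxel) = micro_c * profile(d) + drain_gain * d * <micro_c * profile>_column

i.e. a microvascular laminar profile — middle-layer-weighted for feedforward
drive, depth-uniform for feedback — plus an additive macrovascular
draining-vein term that grows linearly toward the pial surface in proportion
to the column-mean microvascular signal.  Voxel time series are
``baseline * (1 + sum_c psc_c * boxcar_c ⊛ HRF / 100)`` plus AR(1) Gaussian
noise at TR = 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from lamiquartet import design as qdesign
from lamiquartet.events import validate_events
from lamiquartet.glm import HRFParams, condition_regressors

SCENARIOS = ("hypothesis1", "hypothesis2", "null")


class PatchError(ValueError):
    """Patch geometry cannot satisfy its invariants."""


class SimulationError(ValueError):
    """Inconsistent inputs to the time-series simulator."""


# ---------------------------------------------------------------------------
# Equivolume geometry
# ---------------------------------------------------------------------------


def equivolume_depth_ring(r: np.ndarray, r_in: float, r_out: float) -> np.ndarray:
    """Equivolume depth of points at radius ``r`` in an annular cortex.

    For a curved ribbon between radii ``r_in`` (white matter) and ``r_out``
    (pial), equal depth increments enclose equal areas, so
    ``d = (r^2 - r_in^2) / (r_out^2 - r_in^2)``.
    """
    if not 0 < r_in < r_out:
        raise PatchError("need 0 < r_in < r_out")
    return (np.asarray(r, float) ** 2 - r_in**2) / (r_out**2 - r_in**2)


def equivolume_from_equidistant(h: np.ndarray, curvature: float, thickness: float = 1.0) -> np.ndarray:
    """Map equidistant depth fractions ``h`` in [0, 1] to equivolume depth.

    ``curvature`` is the signed curvature of the white-matter surface in units
    of 1/thickness: positive curvature (gyral crown, WM surface convex) dilates
    superficial volume, negative (sulcal fundus) dilates deep volume, and 0
    recovers ``d = h`` exactly (flat-cortex limit).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < -1e-12) or np.any(h > 1 + 1e-12):
        raise PatchError("equidistant depth must lie in [0, 1]")
    if curvature == 0:
        return h.copy()
    radius = 1.0 / abs(curvature)
    t = thickness
    if curvature > 0:
        # WM surface is the inner ring
        return h * (2 * radius + h * t) / (2 * radius + t)
    hh = 1.0 - h
    return 1.0 - hh * (2 * radius + hh * t) / (2 * radius + t)


# ---------------------------------------------------------------------------
# Cortical patch
# ---------------------------------------------------------------------------


@dataclass
class CorticalPatch:
    """Per-voxel geometry and ground truth for one region of interest."""

    u: np.ndarray
    v: np.ndarray
    d_ev: np.ndarray
    curvature: np.ndarray
    roi: np.ndarray  # str per voxel
    true_cluster: np.ndarray  # 'H' | 'V' | 'none'
    column_id: np.ndarray  # int per voxel

    @property
    def n_voxels(self) -> int:
        return len(self.u)

    def column_ids(self) -> np.ndarray:
        return np.unique(self.column_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u": self.u,
                "v": self.v,
                "d_ev": self.d_ev,
                "curvature": self.curvature,
                "roi": self.roi,
                "true_cluster": self.true_cluster,
                "column_id": self.column_id,
            }
        )


def concat_patches(patches: list[CorticalPatch]) -> CorticalPatch:
    """Stack patches voxel-wise, re-indexing column ids to stay unique."""
    offset = 0
    cols = []
    for p in patches:
        cols.append(p.column_id + offset)
        offset += p.column_id.max() + 1
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in patches])
    return CorticalPatch(
        u=cat("u"),
        v=cat("v"),
        d_ev=cat("d_ev"),
        curvature=cat("curvature"),
        roi=cat("roi"),
        true_cluster=cat("true_cluster"),
        column_id=np.concatenate(cols),
    )


def make_patch(
    n_columns: int = 12,
    voxels_per_column: int = 6,
    cluster_fractions: dict[str, float] | None = None,
    curvature_range: tuple[float, float] = (-0.5, 0.5),
    thickness: float = 1.0,
    column_spacing: float = 1.0,
    roi: str = "V1",
    seed: int | np.random.Generator = 0,
    u_offset: float = 0.0,
) -> CorticalPatch:
    """Build a cortical patch of interleaved H/V columns on a (u, v) grid.

    Voxels sit at the centers of ``voxels_per_column`` equidistant depth cells
    and get equivolume depths from a curved-ribbon model with a per-column
    curvature drawn uniformly from ``curvature_range``.  Cluster labels
    alternate H, V (then 'none' for any unassigned remainder) across grid
    positions, are constant within a column, and every column spans all three
    depth tertiles.  Deterministic given the seed.
    """
    if voxels_per_column < 3:
        raise PatchError("voxels_per_column < 3 cannot span three layers")
    if n_columns < 1:
        raise PatchError("need at least one column")
    fractions = {"H": 0.5, "V": 0.5} if cluster_fractions is None else dict(cluster_fractions)
    if sum(fractions.values()) > 1 + 1e-9:
        raise PatchError("cluster fractions sum above 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_h = int(round(fractions.get("H", 0.0) * n_columns))
    n_v = int(round(fractions.get("V", 0.0) * n_columns))
    n_h, n_v = min(n_h, n_columns), min(n_v, n_columns - min(n_h, n_columns))
    labels: list[str] = []
    h_left, v_left = n_h, n_v
    while h_left or v_left:  # strict interleaving H, V, H, V, ...
        if h_left:
            labels.append("H")
            h_left -= 1
        if v_left:
            labels.append("V")
            v_left -= 1
    labels += ["none"] * (n_columns - len(labels))

    n_x = int(np.ceil(np.sqrt(n_columns)))
    h = (np.arange(voxels_per_column) + 0.5) / voxels_per_column
    u_list, v_list, d_list, curv_list, lab_list, col_list = [], [], [], [], [], []
    for c in range(n_columns):
        curv = float(rng.uniform(*curvature_range))
        d = equivolume_from_equidistant(h, curv, thickness)
        tert = np.floor(np.clip(d, 0, 1 - 1e-12) * 3).astype(int)
        if set(tert) != {0, 1, 2}:
            raise PatchError(
                f"column {c} (curvature {curv:.3f}) does not span all three depth tertiles"
            )
        u_list.append(np.full(voxels_per_column, u_offset + (c % n_x) * column_spacing))
        v_list.append(np.full(voxels_per_column, (c // n_x) * column_spacing))
        d_list.append(d)
        curv_list.append(np.full(voxels_per_column, curv))
        lab_list.append(np.full(voxels_per_column, labels[c], dtype=object))
        col_list.append(np.full(voxels_per_column, c))
    return CorticalPatch(
        u=np.concatenate(u_list),
        v=np.concatenate(v_list),
        d_ev=np.concatenate(d_list),
        curvature=np.concatenate(curv_list),
        roi=np.full(n_columns * voxels_per_column, roi, dtype=object),
        true_cluster=np.concatenate(lab_list),
        column_id=np.concatenate(col_list),
    )


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------


def _normalized(profile: Callable[[np.ndarray], np.ndarray]) -> Callable[[np.ndarray], np.ndarray]:
    grid = np.linspace(0, 1, 513)
    mean = float(np.trapezoid(profile(grid), grid))
    return lambda d: profile(np.asarray(d, float)) / mean


def middle_bump_profile(bump_amp: float = 0.5, center: float = 0.5, width: float = 0.2):
    """Feedforward microvascular profile: unit floor plus a Gaussian bump at
    mid-depth (thalamic input layer), normalized to mean 1 over depth."""
    raw = lambda d: 1.0 + bump_amp * np.exp(-0.5 * ((d - center) / width) ** 2)
    return _normalized(raw)


def flat_profile():
    """Feedback microvascular profile: equal weight at all depths."""
    return lambda d: np.ones_like(np.asarray(d, dtype=float))


@dataclass
class LaminarResponseModel:
    """Amplitudes (PSC) and depth weightings of the evoked signal.

    ``beta_pref`` / ``beta_nonpref`` are the microvascular amplitudes of a
    cluster's preferred / non-preferred physical motion condition;
    ``amb_pref`` / ``amb_nonpref`` the percept-matched / unmatched ambiguous
    amplitudes before the multiplicative ``amplitude_scale_ambiguous``
    reduction.  ``drain_gain`` scales the linear macrovascular drainage term.
    With ``drain_gain = 0`` the measured laminar profile equals the
    microvascular profile.
    """

    beta_pref: float = 2.0
    beta_nonpref: float = 0.0
    beta_flicker: float = 0.5
    amb_pref: float = 2.0
    amb_nonpref: float = 0.0
    amplitude_scale_ambiguous: float = 0.5
    drain_gain: float = 1.5
    micro_profile_ff: Callable[[np.ndarray], np.ndarray] = field(default_factory=middle_bump_profile)
    micro_profile_fb: Callable[[np.ndarray], np.ndarray] = field(default_factory=flat_profile)
    profile_physical: str = "ff"
    profile_ambiguous: str = "fb"

    def __post_init__(self) -> None:
        if self.drain_gain < 0:
            raise ValueError("drain_gain must be >= 0")
        if not 0 < self.amplitude_scale_ambiguous <= 1:
            raise ValueError("amplitude_scale_ambiguous must lie in (0, 1]")
        grid = np.linspace(0, 1, 65)
        for name in ("micro_profile_ff", "micro_profile_fb"):
            if np.any(getattr(self, name)(grid) < 0):
                raise ValueError(f"{name} must be non-negative")

    def profile(self, condition_type: str) -> Callable[[np.ndarray], np.ndarray]:
        which = self.profile_physical if condition_type == "physical" else self.profile_ambiguous
        return self.micro_profile_ff if which == "ff" else self.micro_profile_fb

    def micro_amplitudes(self, condition: str, condition_type: str) -> tuple[float, float]:
        """(amplitude for matched cluster, for opposite cluster) of one condition."""
        if condition == "flicker":
            return self.beta_flicker, self.beta_flicker
        if condition_type == "physical":
            return self.beta_pref, self.beta_nonpref
        s = self.amplitude_scale_ambiguous
        return s * self.amb_pref, s * self.amb_nonpref


def condition_psc(patch: CorticalPatch, model: LaminarResponseModel, condition: str, condition_type: str) -> np.ndarray:
    """Per-voxel PSC evoked by one condition: microvascular laminar profile
    plus the depth-linear macrovascular drainage term."""
    if condition == "flicker":
        profile = model.micro_profile_ff  # flicker is a physical (feedforward) stimulus
    else:
        profile = model.profile(condition_type)
    amp_match, amp_opp = model.micro_amplitudes(condition, condition_type)
    axis = {"horizontal": "H", "vertical": "V"}.get(condition)
    micro_amp = np.zeros(patch.n_voxels)
    if condition == "flicker":
        micro_amp[:] = amp_match
    else:
        micro_amp[patch.true_cluster == axis] = amp_match
        micro_amp[np.isin(patch.true_cluster, [c for c in ("H", "V") if c != axis])] = amp_opp
    micro = micro_amp * profile(patch.d_ev)
    # column-mean microvascular signal feeds the ascending-vein term
    _, inv = np.unique(patch.column_id, return_inverse=True)
    sums = np.bincount(inv, weights=micro)
    counts = np.bincount(inv)
    col_mean = (sums / counts)[inv]
    return micro + model.drain_gain * patch.d_ev * col_mean


# ---------------------------------------------------------------------------
# Acquisition + run simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling and noise parameters of the simulated acquisition."""

    tr_s: float = 2.0
    hrf: HRFParams = field(default_factory=HRFParams)
    noise_sd: float = 2.0  # stationary noise SD in PSC units
    ar1: float = 0.3  # lag-1 autocorrelation of the noise
    baseline: float = 1000.0  # arbitrary image intensity

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def ar1_noise(n: int, n_series: int, sd: float, ar1: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian noise, shape (n, n_series), marginal SD ``sd``."""
    if sd == 0:
        return np.zeros((n, n_series))
    burn = 100
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    e = rng.standard_normal((n + burn, n_series)) * innov_sd
    x = lfilter([1.0], [1.0, -ar1], e, axis=0)
    return x[burn:]


def simulate_run(
    patch: CorticalPatch,
    model: LaminarResponseModel,
    schedule: qdesign.RunSchedule,
    events: pd.DataFrame,
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int | np.random.Generator = 0,
    condition_type: str = "physical",
) -> np.ndarray:
    """Simulate one run; returns (volumes x voxels) signal.

    For ``condition_type='physical'`` the motion regressors follow stimulus
    events; for ``'ambiguous'`` they follow percept events (flicker always
    from the stimulus stream).  Deterministic given the seed.
    """
    validate_events(events)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_vol = schedule.n_volumes
    run_s = n_vol * acq.tr_s
    if (events["onset"] + events["duration"] > schedule.total_s + 1e-6).any():
        raise SimulationError("events exceed the scheduled run length")
    src = "percept" if condition_type == "ambiguous" else "stimulus"
    motion = events.loc[(events["source"] == src) & events["trial_type"].isin(("horizontal", "vertical"))]
    flick = events.loc[(events["source"] == "stimulus") & (events["trial_type"] == "flicker")]
    task_events = pd.concat([motion, flick]).sort_values("onset").reset_index(drop=True)
    conditions = ("horizontal", "vertical", "flicker")
    X = condition_regressors(task_events, n_vol, acq.tr_s, conditions, acq.hrf)
    P = np.stack([condition_psc(patch, model, c, condition_type) for c in conditions])
    clean = acq.baseline * (1.0 + X @ P / 100.0)
    noise = ar1_noise(n_vol, patch.n_voxels, acq.noise_sd / 100.0 * acq.baseline, acq.ar1, rng)
    return clean + noise


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class Run:
    name: str
    condition_type: str  # 'physical' | 'ambiguous'
    role: str  # 'localizer' | 'estimation'
    schedule: qdesign.RunSchedule
    events: pd.DataFrame  # stimulus blocks (+ percept stream for ambiguous)
    data: np.ndarray  # volumes x voxels


@dataclass
class CohortUnit:
    subject: int
    hemisphere: str
    patch: CorticalPatch
    models: dict[str, LaminarResponseModel]  # per ROI
    runs: list[Run]


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults follow the experimental design: TR 2 s, 10 s motion blocks, 16 s
    flicker, 20 s fixation bookends, 6 super-block repetitions per run, percept
    dwells from a truncated gamma on [3, 20] s.  ``n_repetitions`` and the
    patch sizes may be reduced for simulation studies; amplitudes and noise
    are the generator's modeled response regime.
    """

    n_physical_runs: int = 2  # first half localizer, second half estimation
    n_ambiguous_runs: int = 1
    n_repetitions: int = 6
    block_s: float = 10.0
    flicker_s: float = 16.0
    fixation_s: float = 20.0
    tr_s: float = 2.0
    n_columns: int = 12
    voxels_per_column: int = 6
    curvature_range: tuple[float, float] = (-0.5, 0.5)
    percept: qdesign.PerceptProcess = field(default_factory=qdesign.PerceptProcess)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    subject_amp_cv: float = 0.1  # lognormal between-subject amplitude spread
    v1_beta_pref: float = 2.0
    v1_beta_nonpref: float = -0.5
    hmt_beta_pref: float = 2.0
    hmt_beta_nonpref: float = 0.5
    beta_flicker: float = 0.5
    drain_gain: float = 1.5
    amplitude_scale_ambiguous: float = 0.5


@dataclass
class SyntheticDataset:
    units: list[CohortUnit]
    scenario: str
    config: CohortConfig
    seed: int

    @property
    def subjects(self) -> list[int]:
        return sorted({u.subject for u in self.units})


def _zeroed(model: LaminarResponseModel) -> LaminarResponseModel:
    return replace(model, beta_pref=0.0, beta_nonpref=0.0, beta_flicker=0.0, amb_pref=0.0, amb_nonpref=0.0)


def scenario_models(scenario: str, config: CohortConfig) -> dict[str, LaminarResponseModel]:
    """Response models per ROI under one feedback scenario.

    * ``hypothesis1`` — feedback targets only the percept-matched V1 cluster.
    * ``hypothesis2`` — feedback drives both V1 clusters equally.
    * ``null`` — no evoked response in either condition (global null for
      calibrating the group tests).

    hMT+ amplitudes are condition-invariant in both hypotheses, with identical
    feedforward laminar profile in both conditions.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    v1 = LaminarResponseModel(
        beta_pref=config.v1_beta_pref,
        beta_nonpref=config.v1_beta_nonpref,
        beta_flicker=config.beta_flicker,
        amb_pref=config.v1_beta_pref,
        amb_nonpref=config.v1_beta_pref if scenario == "hypothesis2" else 0.0,
        amplitude_scale_ambiguous=config.amplitude_scale_ambiguous,
        drain_gain=config.drain_gain,
        profile_physical="ff",
        profile_ambiguous="fb",
    )
    hmt = LaminarResponseModel(
        beta_pref=config.hmt_beta_pref,
        beta_nonpref=config.hmt_beta_nonpref,
        beta_flicker=config.beta_flicker,
        amb_pref=config.hmt_beta_pref,
        amb_nonpref=config.hmt_beta_nonpref,
        amplitude_scale_ambiguous=1.0,  # condition-invariant
        drain_gain=config.drain_gain,
        profile_physical="ff",
        profile_ambiguous="ff",  # laminar organization invariant across conditions
    )
    models = {"V1": v1, "hMT": hmt}
    if scenario == "null":
        models = {roi: _zeroed(m) for roi, m in models.items()}
    return models


def _scale_model(model: LaminarResponseModel, factor: float) -> LaminarResponseModel:
    return replace(
        model,
        beta_pref=model.beta_pref * factor,
        beta_nonpref=model.beta_nonpref * factor,
        beta_flicker=model.beta_flicker * factor,
        amb_pref=model.amb_pref * factor,
        amb_nonpref=model.amb_nonpref * factor,
    )


def make_cohort(
    n_subjects: int = 8,
    hemispheres: int = 2,
    scenario: str = "hypothesis2",
    seed: int = 0,
    config: CohortConfig | None = None,
) -> SyntheticDataset:
    """Simulate a cohort of subjects x hemispheres with V1 and hMT+ patches.

    Each unit (hemisphere) gets its own patch geometry and per-subject
    amplitude factor (lognormal, CV ``subject_amp_cv``), physical runs split
    into localizer and estimation halves, and ambiguous runs driven by a
    subject-specific percept stream shared between the two ROIs.
    Deterministic given ``seed``.
    """
    config = config or CohortConfig()
    base_models = scenario_models(scenario, config)
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    units: list[CohortUnit] = []
    phys_schedule, phys_events = qdesign.build_physical_schedule(
        block_s=config.block_s,
        flicker_s=config.flicker_s,
        n_repetitions=config.n_repetitions,
        fixation_s=config.fixation_s,
        tr_s=config.tr_s,
    )
    amb_schedule, amb_stim_events = qdesign.build_ambiguous_schedule(
        ambiguous_s=4 * 2 * config.block_s,
        flicker_s=config.flicker_s,
        n_repetitions=config.n_repetitions,
        fixation_s=config.fixation_s,
        tr_s=config.tr_s,
    )
    hemi_names = ("LH", "RH")[:hemispheres]
    for s, sseq in enumerate(subj_seeds):
        subj_rng = np.random.default_rng(sseq)
        amp_factor = float(np.exp(subj_rng.normal(0.0, config.subject_amp_cv)))
        models = {roi: _scale_model(m, amp_factor) for roi, m in base_models.items()}
        for hemi in hemi_names:
            v1 = make_patch(
                n_columns=config.n_columns,
                voxels_per_column=config.voxels_per_column,
                curvature_range=config.curvature_range,
                roi="V1",
                seed=subj_rng,
            )
            hmt = make_patch(
                n_columns=config.n_columns,
                voxels_per_column=config.voxels_per_column,
                curvature_range=config.curvature_range,
                roi="hMT",
                seed=subj_rng,
                u_offset=100.0,
            )
            patch = concat_patches([v1, hmt])
            roi_masks = {"V1": patch.roi == "V1", "hMT": patch.roi == "hMT"}
            runs: list[Run] = []
            for r in range(config.n_physical_runs):
                role = "localizer" if r < config.n_physical_runs // 2 + config.n_physical_runs % 2 else "estimation"
                if config.n_physical_runs == 1:
                    role = "localizer+estimation"
                data = _simulate_rois(patch, roi_masks, models, phys_schedule, phys_events, config, subj_rng, "physical")
                runs.append(Run(f"phys{r + 1}", "physical", role, phys_schedule, phys_events, data))
            for r in range(config.n_ambiguous_runs):
                percepts = qdesign.percept_stream_for_run(amb_stim_events, config.percept, subj_rng)
                ev = pd.concat([amb_stim_events, percepts]).sort_values(["source", "onset"]).reset_index(drop=True)
                data = _simulate_rois(patch, roi_masks, models, amb_schedule, ev, config, subj_rng, "ambiguous")
                runs.append(Run(f"amb{r + 1}", "ambiguous", "estimation", amb_schedule, ev, data))
            units.append(CohortUnit(s, hemi, patch, models, runs))
    return SyntheticDataset(units=units, scenario=scenario, config=config, seed=seed)


def _simulate_rois(patch, roi_masks, models, schedule, events, config, rng, condition_type):
    data = np.empty((schedule.n_volumes, patch.n_voxels))
    for roi, mask in roi_masks.items():
        sub = CorticalPatch(
            u=patch.u[mask],
            v=patch.v[mask],
            d_ev=patch.d_ev[mask],
            curvature=patch.curvature[mask],
            roi=patch.roi[mask],
            true_cluster=patch.true_cluster[mask],
            column_id=patch.column_id[mask],
        )
        data[:, mask] = simulate_run(sub, models[roi], schedule, events, config.acquisition, rng, condition_type)
    return data
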