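"""End-to-end driver: simulate (or load) a cohort and run every analysis stage.

Stage order: stimulus/percept design -> laminar BOLD simulation -> PSC
normalization + AR(2) GLM -> winner-take-all clusters -> specificity ->
laminar profiles and slopes -> event-related averages -> group statistics.

Physical runs are split into a localizer half (cluster definition) and an
estimation half (all reported percent-signal-change, specificity, laminar and
ERA quantities), so the voxel selection is statistically independent of the
quantities later compared between conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lamiquartet import era as qera
from lamiquartet import laminar as qlaminar
from lamiquartet.clusters import (
    ClusterAssignment,
    compare_conditions,
    define_clusters,
    summarize_cluster_psc,
)
from lamiquartet.config import AnalysisConfig, PipelineConfig
from lamiquartet.era import SimilarityStat
from lamiquartet.glm import build_design, contrast_t, fit_glm, normalize_psc
from lamiquartet.laminar import DepthBins, SlopeStat
from lamiquartet.specificity import cluster_specificity, voxel_specificity
from lamiquartet.stats import GroupComparison, UndefinedTestError, sem
from lamiquartet.synth import SyntheticDataset, make_cohort

ROIS = ("V1", "hMT")
CONDITION_TYPES = ("physical", "ambiguous")


@dataclass
class UnitResult:
    subject: int
    hemisphere: str
    assignments: dict[str, ClusterAssignment]  # per ROI (thresholded)
    extended: dict[str, ClusterAssignment]  # per ROI (column-extended)
    betas: dict[tuple[str, str], np.ndarray]  # (condition_type, condition) -> voxels
    tmaps: dict[str, np.ndarray]  # localizer H>V t per ROI (full-length, NaN off-ROI)
    trials: dict  # (roi, condition_type, cluster) -> TrialSet


@dataclass
class CohortResults:
    psc_summary: pd.DataFrame
    psc_tests: dict[tuple[str, str], GroupComparison]
    specificity_summary: pd.DataFrame
    specificity_tests: dict[str, GroupComparison]
    profiles: dict[tuple[str, str, str], dict]  # (roi, cluster, ct) -> group layer stats
    differential: dict[tuple[str, str], dict]  # (roi, cluster) -> group differential
    slopes: dict[str, SlopeStat]  # per ROI
    era_curves: dict[tuple[str, str, str], dict]  # (roi, ct, role) -> group curve
    era_similarity: dict[tuple[str, str], SimilarityStat]  # (roi, ct) within-area
    cross_area_similarity: SimilarityStat | None
    recovery: dict[str, float]  # per ROI: label agreement among assigned voxels
    units: list[UnitResult] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        """Machine-readable summary of every group statistic."""

        def cmp(c: GroupComparison | None) -> dict | None:
            if c is None:
                return None
            return {"n": c.n, "statistic": c.statistic, "p": c.p_value, "p_exact": c.p_exact, "p_approx": c.p_approx}

        return {
            "psc_tests": {f"{r}/{c}": cmp(t) for (r, c), t in self.psc_tests.items()},
            "specificity_tests": {r: cmp(t) for r, t in self.specificity_tests.items()},
            "slopes": {
                r: {"mean_slope": float(np.mean(s.slopes)), "p": None if s.comparison is None else s.comparison.p_value}
                for r, s in self.slopes.items()
            },
            "era_similarity": {
                f"{r}/{ct}": None if s.comparison is None else {"mean_rho": float(np.mean(s.rhos)), "p": s.comparison.p_value}
                for (r, ct), s in self.era_similarity.items()
            },
            "cross_area_similarity": None
            if self.cross_area_similarity is None or self.cross_area_similarity.comparison is None
            else {
                "mean_rho": float(np.mean(self.cross_area_similarity.rhos)),
                "p": self.cross_area_similarity.comparison.p_value,
            },
            "recovery": self.recovery,
            "log": self.log,
        }


def _mean_betas(results: list) -> dict[str, np.ndarray]:
    names = results[0].names
    out = {}
    for cond in ("horizontal", "vertical", "flicker"):
        out[cond] = np.mean([r.betas[names.index(cond)] for r in results], axis=0)
    return out


def analyze_unit(unit, analysis: AnalysisConfig, log: list[str], design_cache: dict | None = None) -> UnitResult:
    """Run GLM, cluster definition, extension and trial extraction for one
    (subject, hemisphere) unit."""
    tr = unit.runs[0].schedule.tr_s
    roi_masks = {roi: unit.patch.roi == roi for roi in ROIS}

    glm_by_role: dict[tuple[str, str], list] = {}
    for run in unit.runs:
        normed, valid = normalize_psc(run.data)
        if not valid.all():
            log.append(f"s{unit.subject}{unit.hemisphere} {run.name}: {np.sum(~valid)} zero-mean voxels excluded")
        source = "percept" if run.condition_type == "ambiguous" else "stimulus"
        # schedules repeat across runs and units; reuse the built design
        key = (id(run.events), run.schedule.n_volumes, source)
        design = design_cache.get(key) if design_cache is not None else None
        if design is None:
            design = build_design(
                run.events, run.schedule.n_volumes, tr, source=source, highpass_cycles=analysis.highpass_cycles
            )
            if design_cache is not None:
                design_cache[key] = design
        result = fit_glm(normed, design)
        roles = ("localizer", "estimation") if run.role == "localizer+estimation" else (run.role,)
        for role in roles:
            glm_by_role.setdefault((run.condition_type, role), []).append(result)

    loc_results = glm_by_role[("physical", "localizer")]
    t_loc = np.mean([contrast_t(r) for r in loc_results], axis=0)

    assignments, extended, tmaps = {}, {}, {}
    for roi in ROIS:
        a = define_clusters(t_loc, roi_masks[roi], pct=analysis.pct, roi=roi)
        assignments[roi] = a
        extended[roi] = qlaminar.extend_clusters_columnwise(a, unit.patch, radius=analysis.radius)
        tm = np.full(len(t_loc), np.nan)
        tm[roi_masks[roi]] = t_loc[roi_masks[roi]]
        tmaps[roi] = tm
        log.append(
            f"s{unit.subject}{unit.hemisphere} {roi}: thresholds t>({a.t_high:.2f}) t<({a.t_low:.2f}); "
            f"H={len(a.members('H'))} V={len(a.members('V'))} voxels"
        )

    betas: dict[tuple[str, str], np.ndarray] = {}
    for ct in CONDITION_TYPES:
        est = glm_by_role.get((ct, "estimation"))
        if not est:
            raise RuntimeError(f"no estimation runs for condition type {ct}")
        for cond, b in _mean_betas(est).items():
            betas[(ct, cond)] = b

    trials = {}
    for roi in ROIS:
        for cluster in ("H", "V"):
            members = assignments[roi].members(cluster)
            for ct in CONDITION_TYPES:
                parts = []
                for run in unit.runs:
                    if run.condition_type != ct or "estimation" not in run.role:
                        continue
                    course = run.data[:, members].mean(axis=1)
                    source = "percept" if ct == "ambiguous" else "stimulus"
                    ts = qera.extract_trials(course, run.events, tr, window_tr=analysis.window_tr, source=source)
                    parts.append(ts)
                if parts:
                    trials[(roi, ct, cluster)] = _concat_trials(parts)
    return UnitResult(unit.subject, unit.hemisphere, assignments, extended, betas, tmaps, trials)


def _concat_trials(parts: list[qera.TrialSet]) -> qera.TrialSet:
    return qera.TrialSet(
        values=np.concatenate([p.values for p in parts], axis=0),
        condition=np.concatenate([p.condition for p in parts]),
        duration_s=np.concatenate([p.duration_s for p in parts]),
        valid=np.concatenate([p.valid for p in parts]),
        window_tr=parts[0].window_tr,
    )


def analyze_cohort(dataset: SyntheticDataset, analysis: AnalysisConfig | None = None) -> CohortResults:
    """Run the full analysis chain on a simulated cohort and assemble group
    statistics (PSC comparisons at N = subjects x hemispheres; specificity,
    slope and ERA statistics at subject level)."""
    analysis = analysis or AnalysisConfig()
    log: list[str] = []
    design_cache: dict = {}
    unit_results = [analyze_unit(u, analysis, log, design_cache) for u in dataset.units]
    units_by_subject: dict[int, list[UnitResult]] = {}
    for ur in unit_results:
        units_by_subject.setdefault(ur.subject, []).append(ur)
    subjects = sorted(units_by_subject)
    tr = dataset.units[0].runs[0].schedule.tr_s

    # --- recovery: ground-truth agreement among assigned voxels -----------
    recovery = {}
    for roi in ROIS:
        agree = total = 0
        for u, ur in zip(dataset.units, unit_results):
            labels = ur.assignments[roi].labels
            assigned = labels != "none"
            agree += int(np.sum(labels[assigned] == u.patch.true_cluster[assigned]))
            total += int(np.sum(assigned))
        recovery[roi] = agree / total if total else float("nan")

    # --- cluster PSC summary + Wilcoxon (N = subjects x hemispheres) ------
    rows = []
    for ur in unit_results:
        for roi in ROIS:
            summary = summarize_cluster_psc(ur.assignments[roi], ur.betas)
            for (cluster, ct), m in summary.items():
                rows.append((ur.subject, ur.hemisphere, roi, cluster, ct, m))
    psc_summary = pd.DataFrame(rows, columns=["subject", "hemisphere", "roi", "cluster", "condition_type", "mean_psc"])
    psc_tests = {}
    for roi in ROIS:
        for cluster in ("H", "V"):
            cell = psc_summary.query("roi == @roi and cluster == @cluster")
            try:
                psc_tests[(roi, cluster)] = compare_conditions(cell, mode=analysis.wilcoxon_mode)
            except (UndefinedTestError, Exception) as e:  # degenerate cells logged, not fatal
                if not isinstance(e, UndefinedTestError):
                    raise
                log.append(f"psc test {roi}/{cluster}: undefined ({e})")

    # --- specificity (subject level, N = n_subjects) ----------------------
    srows = []
    for ur in unit_results:
        for roi in ROIS:
            for ct in CONDITION_TYPES:
                s, _ = voxel_specificity(ur.betas[(ct, "horizontal")], ur.betas[(ct, "vertical")])
                cs = cluster_specificity(s, ur.assignments[roi])
                for cluster, (m, _se, n) in cs.items():
                    srows.append((ur.subject, ur.hemisphere, roi, cluster, ct, m, n))
    specificity_summary = pd.DataFrame(
        srows, columns=["subject", "hemisphere", "roi", "cluster", "condition_type", "specificity", "n_voxels"]
    )
    specificity_tests = {}
    for roi in ROIS:
        per_subj = (
            specificity_summary.query("roi == @roi")
            .groupby(["subject", "condition_type"])["specificity"]
            .mean()
            .unstack("condition_type")
            .dropna()
        )
        try:
            from lamiquartet.stats import wilcoxon_signed_rank

            specificity_tests[roi] = wilcoxon_signed_rank(
                per_subj["physical"].to_numpy(), per_subj["ambiguous"].to_numpy(), mode=analysis.wilcoxon_mode
            )
        except UndefinedTestError as e:
            log.append(f"specificity test {roi}: undefined ({e})")

    # --- laminar profiles + differential slopes ---------------------------
    bins = DepthBins()
    prof_stack: dict[tuple[str, str, str], list[np.ndarray]] = {}
    diff_stack: dict[tuple[str, str], list[np.ndarray]] = {}
    slope_by_subject: dict[str, dict[int, list[float]]] = {roi: {} for roi in ROIS}
    for u, ur in zip(dataset.units, unit_results):
        for roi in ROIS:
            cluster_slopes = []
            for cluster in ("H", "V"):
                profs = {}
                try:
                    for ct in CONDITION_TYPES:
                        cond = {"H": "horizontal", "V": "vertical"}[cluster]
                        profs[ct] = qlaminar.laminar_profile(
                            ur.betas[(ct, cond)], ur.extended[roi], u.patch.d_ev, cluster, bins
                        )
                except qlaminar.LayerError as e:
                    log.append(f"laminar {roi}/{cluster} s{ur.subject}{ur.hemisphere}: missing cell ({e})")
                    continue
                for ct in CONDITION_TYPES:
                    prof_stack.setdefault((roi, cluster, ct), []).append(profs[ct].mean)
                d = qlaminar.differential_profile(profs["physical"], profs["ambiguous"])
                diff_stack.setdefault((roi, cluster), []).append(d.mean)
                cluster_slopes.append(qlaminar.profile_slope(d.mean, bins.centers))
            if cluster_slopes:
                slope_by_subject[roi].setdefault(ur.subject, []).append(float(np.mean(cluster_slopes)))

    def group_layers(stack: list[np.ndarray]) -> dict:
        arr = np.asarray(stack)
        return {
            "mean": arr.mean(axis=0).tolist(),
            "sem": [sem(arr[:, k]) for k in range(arr.shape[1])],
            "n": len(arr),
        }

    profiles = {key: group_layers(v) for key, v in prof_stack.items()}
    differential = {key: group_layers(v) for key, v in diff_stack.items()}
    slopes = {}
    for roi in ROIS:
        per_subj = np.array([np.mean(slope_by_subject[roi][s]) for s in subjects])
        slopes[roi] = qlaminar.slope_test(per_subj, mode=analysis.wilcoxon_mode)

    # --- event-related averages -------------------------------------------
    era_curves: dict[tuple[str, str, str], dict] = {}
    era_similarity: dict[tuple[str, str], SimilarityStat] = {}
    subj_role_curves: dict[tuple[str, str, str, int], np.ndarray] = {}
    for roi in ROIS:
        for ct in CONDITION_TYPES:
            role_stack: dict[str, list[np.ndarray]] = {"preferred": [], "not_preferred": []}
            for s in subjects:
                parts = {"H": [], "V": []}
                for ur in units_by_subject[s]:
                    for cluster in ("H", "V"):
                        key = (roi, ct, cluster)
                        if key in ur.trials:
                            parts[cluster].append(ur.trials[key])
                if not (parts["H"] and parts["V"]):
                    log.append(f"era {roi}/{ct}: subject {s} missing cluster trials")
                    continue
                merged = {cl: _concat_trials(ps) for cl, ps in parts.items()}
                try:
                    selected = {cl: qera.select_trials(ts, analysis.min_trial_s) for cl, ts in merged.items()}
                    curves = qera.pool_roles_and_average(selected, tr_s=tr)
                except qera.TrialError as e:
                    log.append(f"era {roi}/{ct}: subject {s} dropped ({e})")
                    continue
                for role, c in curves.items():
                    role_stack[role].append(c.mean)
                    subj_role_curves[(roi, ct, role, s)] = c.mean
            for role, stack in role_stack.items():
                if stack:
                    era_curves[(roi, ct, role)] = group_layers(stack)
            pairs = [
                (subj_role_curves[(roi, ct, "preferred", s)], subj_role_curves[(roi, ct, "not_preferred", s)])
                for s in subjects
                if (roi, ct, "preferred", s) in subj_role_curves and (roi, ct, "not_preferred", s) in subj_role_curves
            ]
            if pairs:
                era_similarity[(roi, ct)] = qera.similarity_test([a for a, _ in pairs], [b for _, b in pairs])

    cross = None
    cross_pairs = []
    for s in subjects:
        keys = [("V1", "ambiguous", r, s) for r in ("preferred", "not_preferred")]
        keys_h = [("hMT", "ambiguous", r, s) for r in ("preferred", "not_preferred")]
        if all(k in subj_role_curves for k in keys + keys_h):
            v1 = np.mean([subj_role_curves[k] for k in keys], axis=0)
            hm = np.mean([subj_role_curves[k] for k in keys_h], axis=0)
            cross_pairs.append((v1, hm))
    if cross_pairs:
        cross = qera.similarity_test([a for a, _ in cross_pairs], [b for _, b in cross_pairs])

    return CohortResults(
        psc_summary=psc_summary,
        psc_tests=psc_tests,
        specificity_summary=specificity_summary,
        specificity_tests=specificity_tests,
        profiles=profiles,
        differential=differential,
        slopes=slopes,
        era_curves=era_curves,
        era_similarity=era_similarity,
        cross_area_similarity=cross,
        recovery=recovery,
        units=unit_results,
        log=log,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> CohortResults:
    """Simulate a cohort from ``config`` and analyze it; optionally write all
    tables, the log and a machine-readable summary under ``out_dir``.

    Stage errors propagate with the failing stage recorded in a note.
    """
    try:
        dataset = make_cohort(
            n_subjects=config.n_subjects,
            hemispheres=config.hemispheres,
            scenario=config.scenario,
            seed=config.seed,
            config=config.cohort,
        )
    except Exception as e:
        e.add_note("pipeline stage: simulate")
        raise
    try:
        results = analyze_cohort(dataset, config.analysis)
    except Exception as e:
        e.add_note("pipeline stage: analyze")
        raise
    if out_dir is not None:
        write_results(results, out_dir, config)
    return results


def write_results(results: CohortResults, out_dir: str | Path, config: PipelineConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.psc_summary.to_csv(out / "cluster_psc.tsv", sep="\t", index=False)
    results.specificity_summary.to_csv(out / "specificity.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(results.summary_dict(), indent=2, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(results.log) + "\n")
    if config is not None:
        config.to_yaml(out / "config.yaml")
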