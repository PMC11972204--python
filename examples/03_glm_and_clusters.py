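"""Fit the AR(2)-corrected GLM on one simulated run and map H/V clusters.

Simulates a physical-motion run for one cortical patch, normalizes to percent
signal change, fits the three-predictor GLM, thresholds the H>V contrast at
the 95th percentile, and scores voxel specificity.
"""

import numpy as np

from lamiquartet.clusters import define_clusters
from lamiquartet.design import build_physical_schedule
from lamiquartet.glm import build_design, contrast_t, fit_glm, normalize_psc
from lamiquartet.specificity import voxel_specificity
from lamiquartet.synth import AcquisitionParams, LaminarResponseModel, make_patch, simulate_run

patch = make_patch(n_columns=12, voxels_per_column=6, seed=1)
schedule, events = build_physical_schedule(n_repetitions=3, fixation_s=12.0)
model = LaminarResponseModel(beta_pref=2.0, beta_nonpref=-0.5)
acq = AcquisitionParams(noise_sd=0.5, ar1=0.3)
data = simulate_run(patch, model, schedule, events, acq, seed=2)

normed, _ = normalize_psc(data)  # y / y_mean * 100
design = build_design(events, schedule.n_volumes, schedule.tr_s, source="stimulus")
result = fit_glm(normed, design)  # OLS + Yule-Walker AR(2) prewhitening, refit
print(f"mean AR(1) coefficient across voxels: {result.ar_coefs[0].mean():.2f} "
      f"(noise was generated with 0.30)")

t = contrast_t(result, "H>V")
assignment = define_clusters(t, pct=95.0)
assigned = assignment.labels != "none"
agree = np.mean(assignment.labels[assigned] == patch.true_cluster[assigned])
print(f"H>V t-map: thresholds t>{assignment.t_high:.2f} / t<{assignment.t_low:.2f}; "
      f"{assigned.sum()} voxels assigned, {100 * agree:.0f}% agree with ground truth")

s, winner = voxel_specificity(result.beta("horizontal"), result.beta("vertical"))
h = assignment.members("H")
print(f"mean specificity of H-cluster voxels: {np.nanmean(s[h]):.2f} "
      f"(0 = equal response to both conditions, 1 = pure preference)")
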