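# Methods

## Signal model

Each voxel in a simulated cortical patch carries tangential coordinates
(u, v), an equivolume depth d ∈ [0, 1] (0 = white-matter side) and a
ground-truth cluster label (H, V or none), constant within a column. The
evoked percent signal change (PSC) of condition c at depth d is

    psc_c(v) = micro_c(v) · profile(d_v) + g · d_v · ⟨micro_c · profile⟩_column

The first term is the microvascular (neuronally specific) response: the
amplitude `micro_c` depends on whether the voxel's column prefers the
condition, and `profile(d)` is a depth weighting normalized to mean 1 —
a unit floor plus a Gaussian bump at mid-depth (amplitude 0.5, width 0.2)
for feedforward drive (thalamic input layers), or constant 1 for feedback.
The second term is the macrovascular draining-vein contribution: ascending
veins accumulate deoxygenation changes from the layers below, so the bias is
proportional to the column-mean microvascular signal and grows linearly with
depth toward the pial surface, with gain `g` (`drain_gain`). With `g = 0`
the measured profile equals the microvascular profile exactly; with shared
`g` and equal amplitudes in two conditions their differential profile is
identically zero — the analytic rationale for differential laminar analysis,
asserted as a test.

The voxel time series is `baseline · (1 + Σ_c psc_c · x_c(t) / 100)` plus
stationary AR(1) Gaussian noise, where `x_c` is the condition boxcar
convolved with a canonical double-gamma HRF on a 0.1 s grid and sampled at
TR. The HRF components' gamma modes sit at the stated delays (response 6 s,
undershoot 16 s, amplitude ratio 6:1, length 32 s), and the convolution is
normalized to unit steady-state gain so that amplitudes — and the fitted
betas on normalized data — are sustained PSC.

### Linearity caveat

The generator is strictly linear: the response to a sustained 10 s block
keeps integrating until block end, so its within-window maximum falls 8–10 s
after onset. Real cortex adapts and the published event-related averages
peak nearer 4–6 s; tests therefore assert the HRF-*lagged rise* of the ERA
rather than an early peak. No neural adaptation, vascular ceiling, motion,
or distortion is modeled.

## Scenarios

* `hypothesis2` (default) — during ambiguous motion both V1 clusters receive
  equal positive feedback (amplitude = scale × physical amplitude, scale 0.5)
  with the flat feedback profile; hMT+ amplitudes and profile are
  condition-invariant.
* `hypothesis1` — only the percept-matched V1 cluster is modulated.
* `null` — no evoked response in either condition. The narrow reading
  (physical response present, ambiguous absent) would leave the
  physical-vs-ambiguous comparisons with a true effect and no defined type-I
  rate, so the global no-response null is used for calibrating every group
  test.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| TR | 2 | s | acquisition sampling of the design |
| motion block / flicker / fixation | 10 / 16 / 20 | s | stated block scheme |
| super-block repetitions | 6 | — | stated scheme (6 × 96 s + bookends = 616 s, 308 volumes; the block scheme is treated as authoritative over the printed 309) |
| dwell law | gamma(shape 3, mean 6 s) truncated to [3, 20] s | s | stated range; right-skewed dwell distributions are standard for bistable perception; mean/shape config-exposed |
| β preferred (V1, hMT+) | 2.0 | PSC | strong physical response regime |
| β non-preferred V1 / hMT+ | −0.5 / +0.5 | PSC | published ERA polarity: suppression in V1, weak positive in hMT+ |
| ambiguous amplitude scale | 0.5 | — | roughly halved feedback-state amplitude |
| drain_gain | 1.5 | — | yields the monotone superficial increase of the feedforward profile over the middle-layer bump |
| noise SD / AR(1) | 2.0 PSC / 0.3 | — | submillimeter GE-EPI noise regime at full problem size |
| baseline intensity | 1000 | a.u. | arbitrary; all downstream math is PSC (tested invariant) |
| percentile threshold | 95 | — | stated cluster rule (lower tail for V by symmetry) |
| extension radius | 0.39 | (u, v) units | stated cylinder radius, read in generator units |
| high-pass | 5 cycles/run | — | stated cutoff for 6-repetition runs (= repetitions − 1) |
| ERA window / minimum trial | 5 TR / 10 s | — | stated trial-matching rule |

## Analysis pipeline

Physical runs are split into a **localizer** half (cluster definition from
the H>V AR(2)-corrected contrast t map, per ROI and hemisphere) and an
**estimation** half (all reported PSC, specificity, laminar and ERA
quantities). The published analysis uses the same runs for both; on
synthetic nulls that selection biases the selected voxels' physical betas
upward and would confound the physical-vs-ambiguous comparisons, so the
split is adopted as this package's design choice.

Group statistics follow the study's levels: cluster-PSC comparisons pair
subject × hemisphere measures (N = 16); specificity, differential-slope and
ERA-similarity tests operate per subject (N = 8) after averaging hemispheres
and clusters. All use the two-sided Wilcoxon signed-rank test — exact by
full 2^n sign enumeration for n ≤ 25 (midranks when absolute differences
tie, where the tabulated distribution does not apply), normal approximation
with continuity correction above; both p-values are always reported.
Spearman correlations on the 6-sample ERA window are deliberately coarse
(average ranks for ties), mirroring the published procedure.

### Numerical choices

* Percentiles use linear interpolation; threshold ties are excluded (strict
  inequality), keeping clusters ≤ 5 % of the ROI.
* Column extension: nearest assigned voxel wins; among exactly equidistant
  voxels (several assigned voxels in one column) the majority label wins,
  then lowest voxel index. Radius 0 reduces to own-column labeling.
* Contrast balancing drops whole events from the over-represented condition,
  largest first among events that do not overshoot the one-TR tolerance,
  with seeded tie-breaking.
* ERA onsets snap to the nearest earlier volume (no interpolation); trials
  whose 5-TR window would cross the run end, or whose onset value is zero,
  are dropped/flagged. Percept trials under 10 s are excluded, survivors
  truncated to the window for a balanced average.
* Zero-residual (noiseless) voxels skip AR estimation and return a capped
  finite t sentinel with a warning.
* Yule–Walker AR coefficients are clipped to (−0.98, 0.98) for stationarity.
* Degenerate inputs raise typed errors (empty percept table, all-equal t,
  empty layers, all-zero differences, events beyond the run).

## Problem sizes in tests

Replicate studies use a reduced configuration: 3 super-block repetitions
(12 s bookends, 156 volumes), 12-column patches of 6 voxels, one localizer +
one estimation physical run and one ambiguous run per hemisphere; the null
calibration study further thins columns to 3 voxels and 2 repetitions. The
reduced configurations keep `noise_sd` at 0.5 instead of 2.0 by variance
matching (one estimation run instead of three, half the volumes, about a
third of the cluster voxels ⇒ roughly 4× the estimation SD), so cluster-level
estimation SNR matches the full-size regime; rank-based group tests are
scale-invariant, so null calibration is unaffected by this choice.

## What the generator does and does not show

Passing tests demonstrate that the pipeline recovers injected cluster maps,
amplitude reductions, laminar slopes and ERA signatures under the stated
linear signal model with stationary AR(1) noise, and that the group tests
are calibrated when no signal is present. They do not validate the
pipeline against physiological nonlinearity (adaptation, vascular ceiling),
spatially correlated noise, motion or registration error, draining-vein
geometry beyond the linear depth term (a lower-triangular leakage
alternative would fit behind the same `condition_psc` contract), or real
inter-subject variability beyond a lognormal amplitude factor (CV 0.1).

### A known bias of the specificity comparison

The specificity score is a function of the *angle* of the (β_H, β_V)
estimate pair. Under the no-response null that angle distribution is set by
the correlation of the two beta estimates, which differs between the block
design and the contiguous percept-driven design (≈ 0.96 vs ≈ 0.93 from
(XᵀX)⁻¹): noise-only specificity is therefore systematically higher for the
ambiguous design, and the physical-vs-ambiguous specificity comparison
rejects slightly above the nominal rate on pure noise (≈ 0.08–0.13 at
α = 0.05 instead of 0.05). This is a property of the measure itself, not of
the test; with real signal present the effect direction makes the
hypothesis-2 comparison (physical > ambiguous specificity) conservative.
The calibration suite reports it honestly rather than masking it.
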