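"""Normalization, high-pass, design building and the AR(2)-corrected GLM."""

import numpy as np
import pytest
from scipy import stats

from lamiquartet.design import build_physical_schedule
from lamiquartet.events import make_events
from lamiquartet.glm import (
    DesignError,
    FitError,
    T_SENTINEL,
    balance_events,
    build_design,
    contrast_t,
    dct_basis,
    double_gamma_hrf,
    fit_glm,
    highpass,
    n_dct_for_cutoff,
    normalize_psc,
)


class TestNormalize:
    def test_constant_series_maps_to_100(self):
        out, valid = normalize_psc(np.full((20, 1), 500.0))
        assert np.allclose(out, 100.0) and valid.all()

    def test_mean_100_series_is_fixed_point(self):
        series = np.array([[90.0], [110.0]])
        out, _ = normalize_psc(series)
        assert np.allclose(out, series)

    def test_idempotent_after_first_pass(self):
        rng = np.random.default_rng(0)
        data = 800 + 50 * rng.standard_normal((40, 5))
        once, _ = normalize_psc(data)
        twice, _ = normalize_psc(once)
        assert np.allclose(once, twice)

    def test_zero_mean_voxel_flagged_not_propagated(self):
        data = np.column_stack([np.ones(10) * 5, np.zeros(10)])
        out, valid = normalize_psc(data)
        assert valid.tolist() == [True, False]
        assert np.isnan(out[:, 1]).all() and np.isfinite(out[:, 0]).all()


class TestHighpass:
    def test_slow_drift_projected_out(self):
        n, tr = 150, 2.0
        # discrete-cosine drift at 2 cycles per run (basis index k = 4)
        drift = dct_basis(n, 10)[:, 3:4] * 7.5
        resid = highpass(drift, tr, cycles_per_run=5)
        assert (resid**2).sum() < 1e-10 * (drift**2).sum()

    def test_white_noise_variance_reduced_by_subspace_dim(self, rng):
        """Projecting out k orthonormal columns removes k/n of the variance in
        expectation (trace identity)."""
        n, tr, cycles, v = 200, 2.0, 5.0, 4000
        k = n_dct_for_cutoff(n, tr, cycles)
        noise = rng.standard_normal((n, v))
        filt = highpass(noise, tr, cycles)
        ratio = (filt**2).sum() / (noise**2).sum()
        expected = 1 - k / n
        se = np.sqrt(2 * k) / n / np.sqrt(v)  # var of chi2_k/n, averaged over voxels
        assert abs(ratio - expected) < 3 * se

    def test_zero_series_stays_zero(self):
        assert np.allclose(highpass(np.zeros((50, 2)), 2.0, 5), 0.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(DesignError):
            highpass(np.zeros((20, 1)), 2.0, cycles_per_run=15)

    def test_dct_column_count_is_twice_cycles(self):
        assert n_dct_for_cutoff(308, 2.0, 5.0) == 10
        assert dct_basis(308, 10).shape == (308, 10)


class TestBuildDesign:
    def test_three_task_columns_for_physical_defaults(self):
        schedule, events = build_physical_schedule()
        d = build_design(events, schedule.n_volumes, 2.0, source="stimulus")
        assert d.task_names == ("horizontal", "vertical", "flicker")
        assert d.task.shape[1] == 3 and d.rank_deficient_tasks == ()

    def test_single_block_peak_delayed_by_hrf(self):
        events = make_events([(0.0, 10.0, "horizontal", "stimulus")])
        d = build_design(events, 30, 2.0, highpass_cycles=None)
        col = d.task[:, 0]
        assert col.argmax() * 2.0 >= 4.0

    def test_empty_condition_flagged_rank_deficient(self):
        events = make_events([(0.0, 10.0, "horizontal", "stimulus")])
        d = build_design(events, 30, 2.0, highpass_cycles=None)
        assert set(d.rank_deficient_tasks) == {"vertical", "flicker"}

    def test_unknown_condition_rejected(self):
        events = make_events([(0.0, 10.0, "horizontal", "stimulus")])
        events.loc[0, "trial_type"] = "diagonal"
        with pytest.raises(DesignError):
            build_design(events, 30, 2.0)

    def test_percept_source_selects_percept_motion_events(self):
        events = make_events(
            [
                (0.0, 80.0, "ambiguous", "stimulus"),
                (80.0, 16.0, "flicker", "stimulus"),
                (0.0, 40.0, "horizontal", "percept"),
                (40.0, 40.0, "vertical", "percept"),
            ]
        )
        d = build_design(events, 48, 2.0, source="percept", highpass_cycles=None)
        assert d.rank_deficient_tasks == ()
        # percept-locked horizontal regressor rises in the first half only
        assert d.task[:18, 0].max() > 0.5 and d.task[30:, 0].max() < 0.6


def _simulate_known(betas, n=160, tr=2.0, noise=None, seed=0):
    """Small block design with known injected amplitudes."""
    rows, t = [], 10.0
    conds = ["horizontal", "vertical", "flicker"]
    for i in range(12):
        rows.append((t, 10.0, conds[i % 3], "stimulus"))
        t += 12.0
    events = make_events(rows)
    design = build_design(events, n, tr, highpass_cycles=None)
    y = design.task @ np.asarray(betas) + 100.0
    rng = np.random.default_rng(seed)
    data = y[:, None] + (noise(rng, n) if noise else 0.0)
    if data.ndim == 1:
        data = data[:, None]
    return design, data


class TestFitGLM:
    def test_noiseless_recovery_within_1e6(self):
        design, data = _simulate_known([2.0, -1.0, 0.5])
        res = fit_glm(data, design)
        assert np.allclose(res.beta("horizontal"), 2.0, atol=1e-6)
        assert np.allclose(res.beta("vertical"), -1.0, atol=1e-6)
        assert np.allclose(res.beta("flicker"), 0.5, atol=1e-6)

    def test_rank_deficient_design_rejected(self):
        events = make_events([(0.0, 10.0, "horizontal", "stimulus")])
        design = build_design(events, 30, 2.0, highpass_cycles=None)
        with pytest.raises(FitError):
            fit_glm(np.random.default_rng(0).standard_normal((30, 2)) + 100, design)

    def test_ar_coefficients_estimated_from_noise(self, rng):
        from lamiquartet.synth import ar1_noise

        design, clean = _simulate_known([0.0, 0.0, 0.0], n=160)
        data = clean + ar1_noise(160, 300, sd=2.0, ar1=0.5, rng=rng)
        res = fit_glm(data, design)
        assert abs(res.ar_coefs[0].mean() - 0.5) < 0.1

    def test_type_one_error_rate_calibrated_under_ar1_noise(self):
        """|t| > t_crit at nominal alpha=0.05 occurs at the nominal rate
        (within binomial 3 SE) for AR(1)=0.4 noise and null betas."""
        from lamiquartet.design import build_physical_schedule
        from lamiquartet.synth import ar1_noise

        schedule, events = build_physical_schedule()
        n = schedule.n_volumes
        design = build_design(events, n, 2.0, source="stimulus", highpass_cycles=5)
        rng = np.random.default_rng(2024)
        nv = 2000
        data = 100.0 + ar1_noise(n, nv, sd=2.0, ar1=0.4, rng=rng)
        res = fit_glm(data, design)
        t = contrast_t(res)
        crit = stats.t.ppf(0.975, res.df)
        rate = np.mean(np.abs(t) > crit)
        se = np.sqrt(0.05 * 0.95 / nv)
        assert abs(rate - 0.05) < 3 * se

    def test_swapping_contrast_labels_negates_t(self, rng):
        design, clean = _simulate_known([1.0, 0.3, 0.0])
        data = clean + rng.standard_normal(clean.shape)
        res = fit_glm(data, design)
        assert np.allclose(contrast_t(res, "H>V"), -contrast_t(res, "V>H"))

    def test_noiseless_contrast_returns_capped_sentinel(self):
        design, data = _simulate_known([2.0, 0.5, 0.0])
        res = fit_glm(data, design)
        with pytest.warns(RuntimeWarning):
            t = contrast_t(res)
        assert np.all(t == T_SENTINEL)

    def test_psc_betas_invariant_to_baseline_intensity(self):
        """Betas on normalized data do not depend on the generator's
        arbitrary image intensity."""
        from lamiquartet.design import RunSchedule
        from lamiquartet.synth import AcquisitionParams, LaminarResponseModel, make_patch, simulate_run

        patch = make_patch(n_columns=4, voxels_per_column=3, curvature_range=(0.0, 0.0), seed=0)
        schedule, events = build_physical_schedule(n_repetitions=1, fixation_s=10.0)
        model = LaminarResponseModel(beta_pref=1.5, drain_gain=0.0, profile_physical="fb")
        betas = {}
        for base in (1000.0, 4000.0):
            acq = AcquisitionParams(noise_sd=0.5, ar1=0.2, baseline=base)
            data = simulate_run(patch, model, schedule, events, acq, seed=11)
            normed, _ = normalize_psc(data)
            design = build_design(events, schedule.n_volumes, 2.0, source="stimulus", highpass_cycles=None)
            betas[base] = fit_glm(normed, design).beta("horizontal")
        assert np.allclose(betas[1000.0], betas[4000.0], atol=1e-8)


class TestBalancing:
    def _uneven_events(self):
        return make_events(
            [
                (0.0, 20.0, "horizontal", "percept"),
                (20.0, 5.0, "vertical", "percept"),
                (25.0, 12.0, "horizontal", "percept"),
                (37.0, 5.0, "vertical", "percept"),
                (42.0, 6.0, "horizontal", "percept"),
            ]
        )

    def test_totals_matched_within_one_tr(self):
        balanced = balance_events(self._uneven_events(), tr_s=2.0, seed=0)
        th = balanced.loc[balanced.trial_type == "horizontal", "duration"].sum()
        tv = balanced.loc[balanced.trial_type == "vertical", "duration"].sum()
        assert abs(th - tv) <= 2.0 + 1e-9

    def test_whole_events_dropped_largest_admissible_first(self):
        # excess = 28: drop the 20 s event, then (12 s would overshoot) the 6 s
        balanced = balance_events(self._uneven_events(), tr_s=2.0, seed=0)
        dropped = set(self._uneven_events().onset) - set(balanced.onset)
        assert dropped == {0.0, 42.0}

    def test_deterministic_given_seed(self):
        a = balance_events(self._uneven_events(), tr_s=2.0, seed=5)
        b = balance_events(self._uneven_events(), tr_s=2.0, seed=5)
        assert a.equals(b)


def test_double_gamma_peak_near_six_seconds():
    t = np.linspace(0, 32, 3201)
    h = double_gamma_hrf(t)
    assert abs(t[h.argmax()] - 6.0) < 1.0 and h.max() == pytest.approx(1.0)
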