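"""Synthetic patch geometry and laminar BOLD generation."""

import numpy as np
import pytest

from lamiquartet.design import build_physical_schedule
from lamiquartet.glm import HRFParams, condition_regressors
from lamiquartet.synth import (
    AcquisitionParams,
    CohortConfig,
    LaminarResponseModel,
    PatchError,
    SimulationError,
    ar1_noise,
    condition_psc,
    equivolume_depth_ring,
    equivolume_from_equidistant,
    flat_profile,
    make_cohort,
    make_patch,
    middle_bump_profile,
    scenario_models,
    simulate_run,
)


class TestEquivolumeDepth:
    def test_ring_area_fraction(self):
        # annulus 2..3, point at 2.5: (2.5^2-4)/(9-4) = 0.45
        assert equivolume_depth_ring(2.5, 2.0, 3.0) == pytest.approx(0.45)

    def test_zero_curvature_reduces_to_equidistant(self):
        h = np.linspace(0, 1, 11)
        assert np.allclose(equivolume_from_equidistant(h, 0.0), h)

    def test_curvature_zero_limit_is_continuous(self):
        h = np.linspace(0, 1, 11)
        near = equivolume_from_equidistant(h, 1e-9)
        assert np.allclose(near, h, atol=1e-8)

    @pytest.mark.parametrize("curv", [-0.8, -0.2, 0.3, 0.9])
    def test_endpoints_and_monotonicity(self, curv):
        h = np.linspace(0, 1, 21)
        d = equivolume_from_equidistant(h, curv)
        assert d[0] == pytest.approx(0.0) and d[-1] == pytest.approx(1.0)
        assert (np.diff(d) > 0).all()


class TestMakePatch:
    def test_each_column_spans_three_tertiles(self, curved_patch):
        for cid in curved_patch.column_ids():
            d = curved_patch.d_ev[curved_patch.column_id == cid]
            assert set(np.floor(np.clip(d, 0, 1 - 1e-12) * 3).astype(int)) == {0, 1, 2}

    def test_cluster_labels_constant_within_columns(self, curved_patch):
        for cid in curved_patch.column_ids():
            labels = curved_patch.true_cluster[curved_patch.column_id == cid]
            assert len(set(labels)) == 1

    def test_depth_increases_within_each_column(self, curved_patch):
        for cid in curved_patch.column_ids():
            d = curved_patch.d_ev[curved_patch.column_id == cid]
            assert (np.diff(d) > 0).all()

    def test_interleaving_and_fractions(self):
        p = make_patch(n_columns=10, cluster_fractions={"H": 0.5, "V": 0.5}, seed=0)
        per_col = [p.true_cluster[p.column_id == c][0] for c in p.column_ids()]
        assert per_col.count("H") == 5 and per_col.count("V") == 5
        assert per_col[:4] == ["H", "V", "H", "V"]

    def test_deterministic_given_seed(self):
        a = make_patch(seed=3)
        b = make_patch(seed=3)
        assert np.allclose(a.d_ev, b.d_ev) and (a.true_cluster == b.true_cluster).all()

    def test_too_few_voxels_per_column_rejected(self):
        with pytest.raises(PatchError):
            make_patch(voxels_per_column=2)

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(PatchError):
            make_patch(cluster_fractions={"H": 0.7, "V": 0.7})


class TestConditionPsc:
    def test_drain_zero_flat_profile_equals_micro_amplitude(self, flat_patch):
        model = LaminarResponseModel(
            beta_pref=1.5, beta_nonpref=0.0, drain_gain=0.0, profile_physical="fb"
        )
        psc = condition_psc(flat_patch, model, "horizontal", "physical")
        h = flat_patch.true_cluster == "H"
        assert np.allclose(psc[h], 1.5) and np.allclose(psc[~h], 0.0)

    def test_drain_adds_linear_depth_term(self, flat_patch):
        base = LaminarResponseModel(beta_pref=2.0, drain_gain=0.0, profile_physical="fb")
        drained = LaminarResponseModel(beta_pref=2.0, drain_gain=1.0, profile_physical="fb")
        p0 = condition_psc(flat_patch, base, "horizontal", "physical")
        p1 = condition_psc(flat_patch, drained, "horizontal", "physical")
        h = flat_patch.true_cluster == "H"
        # column-mean micro = 2.0, so the drainage term is exactly 2*d
        assert np.allclose(p1[h] - p0[h], 2.0 * flat_patch.d_ev[h])

    def test_profiles_are_mean_one_and_nonnegative(self):
        grid = np.linspace(0, 1, 2001)
        for prof in (middle_bump_profile(), flat_profile()):
            vals = prof(grid)
            assert (vals >= 0).all()
            assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-3)


class TestSimulateRun:
    def _long_block_setup(self):
        """One 120 s horizontal block, much longer than the HRF, so the
        response plateau equals the injected sustained amplitude."""
        from lamiquartet.design import RunSchedule
        from lamiquartet.events import make_events

        schedule = RunSchedule((("horizontal", 120.0), ("fixation", 40.0)), tr_s=2.0)
        events = make_events([(0.0, 120.0, "horizontal", "stimulus"), (120.0, 40.0, "fixation", "stimulus")])
        return schedule, events

    def test_noiseless_peak_psc_equals_injected_beta(self, flat_patch, noiseless_acq):
        schedule, events = self._long_block_setup()
        model = LaminarResponseModel(beta_pref=2.0, drain_gain=0.0, profile_physical="fb")
        data = simulate_run(flat_patch, model, schedule, events, noiseless_acq, seed=0)
        h = flat_patch.true_cluster == "H"
        plateau = data[50, h]  # t = 100 s, well past the HRF transient
        plateau_psc = (plateau / noiseless_acq.baseline - 1.0) * 100.0
        assert np.allclose(plateau_psc, 2.0, atol=1e-6)

    def test_doubling_beta_doubles_noiseless_response(self, flat_patch, noiseless_acq):
        schedule, events = self._long_block_setup()
        m1 = LaminarResponseModel(beta_pref=1.0, drain_gain=0.0, profile_physical="fb")
        m2 = LaminarResponseModel(beta_pref=2.0, drain_gain=0.0, profile_physical="fb")
        d1 = simulate_run(flat_patch, m1, schedule, events, noiseless_acq, seed=0)
        d2 = simulate_run(flat_patch, m2, schedule, events, noiseless_acq, seed=0)
        b = noiseless_acq.baseline
        assert np.allclose(d2 - b, 2.0 * (d1 - b), atol=1e-9)

    def test_feedforward_with_drain_increases_toward_surface(self, flat_patch, noiseless_acq):
        """Layer-mean response strictly increases deep -> superficial, the
        draining-vein signature of the feedforward condition."""
        schedule, events = self._long_block_setup()
        model = LaminarResponseModel(beta_pref=2.0, drain_gain=1.0, profile_physical="ff")
        data = simulate_run(flat_patch, model, schedule, events, noiseless_acq, seed=0)
        h = flat_patch.true_cluster == "H"
        peak = data[50, h]  # plateau sample
        d = flat_patch.d_ev[h]
        layer = np.floor(np.clip(d, 0, 1 - 1e-9) * 3).astype(int)
        means = [peak[layer == k].mean() for k in range(3)]
        assert means[0] < means[1] < means[2]

    def test_noise_lag1_autocorrelation_matches_ar1(self, rng):
        """Sample lag-1 autocorrelation of a noise-only run is within 3 SE of
        the AR(1) coefficient (large-sample theory oracle)."""
        phi = 0.4
        n, v = 4000, 100
        x = ar1_noise(n, v, sd=1.0, ar1=phi, rng=rng)
        xc = x - x.mean(axis=0)
        r1 = (xc[1:] * xc[:-1]).sum(axis=0) / (xc**2).sum(axis=0)
        # allow for the O(1/n) small-sample bias of the sample ACF
        bias = -(1 + 4 * phi) / n
        se = np.sqrt((1 - phi**2) / n) / np.sqrt(v)
        assert abs(r1.mean() - (phi + bias)) < 3 * se

    def test_events_exceeding_run_rejected(self, flat_patch, noiseless_acq):
        from lamiquartet.design import RunSchedule
        from lamiquartet.events import make_events

        schedule = RunSchedule((("horizontal", 20.0),), tr_s=2.0)
        events = make_events([(0.0, 50.0, "horizontal", "stimulus")])
        with pytest.raises(SimulationError):
            simulate_run(flat_patch, LaminarResponseModel(), schedule, events, noiseless_acq, seed=0)


class TestCohort:
    def test_null_scenario_has_no_evoked_response(self):
        models = scenario_models("null", CohortConfig())
        for m in models.values():
            assert m.beta_pref == m.beta_nonpref == m.amb_pref == m.amb_nonpref == 0.0

    def test_hypothesis2_drives_both_v1_clusters_equally(self):
        models = scenario_models("hypothesis2", CohortConfig())
        assert models["V1"].amb_pref == models["V1"].amb_nonpref > 0

    def test_hypothesis1_modulates_only_matched_cluster(self):
        models = scenario_models("hypothesis1", CohortConfig())
        assert models["V1"].amb_pref > 0 and models["V1"].amb_nonpref == 0.0

    def test_hmt_amplitudes_condition_invariant(self):
        for scenario in ("hypothesis1", "hypothesis2"):
            m = scenario_models(scenario, CohortConfig())["hMT"]
            assert m.amb_pref == m.beta_pref and m.amb_nonpref == m.beta_nonpref
            assert m.amplitude_scale_ambiguous == 1.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_models("hypothesis3", CohortConfig())

    def test_cohort_structure_and_volume_counts(self):
        cfg = CohortConfig(n_repetitions=1, fixation_s=8.0, n_columns=4, voxels_per_column=3)
        ds = make_cohort(n_subjects=2, hemispheres=2, scenario="null", seed=0, config=cfg)
        assert len(ds.units) == 4
        for unit in ds.units:
            for run in unit.runs:
                assert run.data.shape == (run.schedule.n_volumes, unit.patch.n_voxels)

    def test_cohort_deterministic_given_seed(self):
        cfg = CohortConfig(n_repetitions=1, fixation_s=8.0, n_columns=4, voxels_per_column=3)
        a = make_cohort(2, 1, "hypothesis2", seed=5, config=cfg)
        b = make_cohort(2, 1, "hypothesis2", seed=5, config=cfg)
        assert np.allclose(a.units[0].runs[0].data, b.units[0].runs[0].data)
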