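"""RGR, region summaries, d', dose arithmetic and the fitted models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from campari import (
    DecayCohortSpec,
    DoseResponseModel,
    DoseSpec,
    ExponentialDecayModel,
    OpticalModel,
    PhotoconversionModel,
    StimulusProtocol,
    SyntheticScene,
    compute_rgr,
    correct_cell_table,
    cycles_for_dose,
    dprime,
    fit_corrections,
    integrate_grating_response,
    light_dose,
    render_scene,
    simulate_decay_cohort,
    simulate_grating_traces,
    summarize_region,
)
from campari.segmentation import extract_cell_fluorescence


def _table(green_corr, red_corr, phase="post", **extra):
    n = len(green_corr)
    base = {"cell_id": np.arange(1, n + 1), "region": "V1m", "hemisphere": "left",
            "depth": 50.0, "phase": phase, "green_corr": green_corr,
            "red_corr": red_corr, "qc_ok": True}
    base.update(extra)
    return pd.DataFrame(base)


class TestComputeRgr:
    def test_simple_division(self):
        out = compute_rgr(_table([95.0], [33.5]))
        assert out.loc[0, "rgr"] == pytest.approx(33.5 / 95.0)

    def test_paired_variant_zero_when_red_unchanged(self):
        t = pd.concat([_table([100.0], [12.0], phase="post"),
                       _table([110.0], [12.0], phase="pre")], ignore_index=True)
        out = compute_rgr(t, variant="paired")
        assert out.loc[0, "rgr"] == pytest.approx(0.0)

    def test_qc_failed_cells_excluded(self):
        t = _table([95.0, -1.0], [33.5, 5.0])
        t.loc[1, "qc_ok"] = False
        assert len(compute_rgr(t)) == 1

    def test_noiseless_pipeline_recovers_true_rgr_exactly(self):
        """simulate -> correct -> extract -> RGR equals the generator's truth."""
        scene = SyntheticScene.random(n_cells=25, shape=(12, 220, 220), seed=5)
        opt = OpticalModel(dark_green=5, dark_red=7, contamination_ratio=0.12,
                           autofluor_intercept={"left": 3.0},
                           shot_noise_scale=0.0, read_noise_sd=0.0)
        pc = PhotoconversionModel()
        meta = {c.cell_id: c for c in scene.cells}

        pre_stack, labels = render_scene(scene, opt, pc, dose=0, phase="pre", seed=0)
        pre = extract_cell_fluorescence(labels, pre_stack.green, pre_stack.red, phase="pre")
        pre["hemisphere"] = [meta[i].hemisphere for i in pre["cell_id"]]
        params = fit_corrections(pre, dark_green=opt.dark_green, dark_red=opt.dark_red)

        post_stack, _ = render_scene(scene, opt, pc, dose=300, phase="post", seed=0)
        post = extract_cell_fluorescence(labels, post_stack.green, post_stack.red, phase="post")
        post["hemisphere"] = [meta[i].hemisphere for i in post["cell_id"]]
        post["region"] = [meta[i].region for i in post["cell_id"]]
        rgr = compute_rgr(correct_cell_table(post, params))
        expected = [pc.true_rgr(300.0, meta[i].activity) for i in rgr["cell_id"]]
        np.testing.assert_allclose(rgr["rgr"], expected, rtol=1e-7, atol=1e-9)

    def test_noisy_pipeline_rank_correlation(self):
        """With default noise the recovered RGR ranks cells by true activity
        (Spearman rho >= 0.95)."""
        acts = np.linspace(0.02, 0.98, 40)
        scene = SyntheticScene.random(n_cells=40, shape=(12, 280, 280),
                                      activity=acts, seed=8)
        opt = OpticalModel()  # default noise on
        pc = PhotoconversionModel()
        meta = {c.cell_id: c for c in scene.cells}
        pre_stack, labels = render_scene(scene, opt, pc, dose=0, phase="pre", seed=1)
        pre = extract_cell_fluorescence(labels, pre_stack.green, pre_stack.red, phase="pre")
        pre["hemisphere"] = "left"
        params = fit_corrections(pre, dark_green=opt.dark_green, dark_red=opt.dark_red)
        post_stack, _ = render_scene(scene, opt, pc, dose=300, phase="post", seed=2)
        post = extract_cell_fluorescence(labels, post_stack.green, post_stack.red, phase="post")
        post["hemisphere"] = "left"
        rgr = compute_rgr(correct_cell_table(post, params))
        truth = np.array([meta[i].activity for i in rgr["cell_id"]])
        rho = sps.spearmanr(rgr["rgr"], truth).statistic
        assert rho >= 0.95


class TestSummarizeRegion:
    def test_median_of_three(self):
        t = _table([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        t["rgr"] = [0.1, 0.2, 0.3]
        s = summarize_region(t)
        assert s.loc[0, "median_rgr"] == pytest.approx(0.2)
        assert s.loc[0, "n_cells"] == 3

    def test_constant_values_have_zero_percentile_range(self):
        t = _table([1.0] * 5, [0.2] * 5)
        t["rgr"] = 0.2
        s = summarize_region(t)
        assert s.loc[0, "range_5_95"] == pytest.approx(0.0)

    def test_lognormal_percentiles_match_closed_form(self, rng):
        mu, sigma, n = -1.0, 0.5, 200_000
        t = pd.DataFrame({"region": "V1m", "rgr": rng.lognormal(mu, sigma, n)})
        s = summarize_region(t)
        for p, col in [(5, "p5"), (25, "p25"), (75, "p75"), (95, "p95")]:
            expected = np.exp(mu + sigma * sps.norm.ppf(p / 100))
            assert s.loc[0, col] == pytest.approx(expected, rel=0.01)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_region(pd.DataFrame({"region": [], "rgr": []}))


class TestDprime:
    def test_identical_groups_zero(self):
        assert dprime([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_hand_computed_example(self):
        # (0.4-0.1)/sqrt(0.5*(0.04+0.01))
        got = dprime([0.2, 0.4, 0.6], [0.0, 0.1, 0.2])
        assert got == pytest.approx(0.3 / np.sqrt(0.025))
        assert got == pytest.approx(1.8973665961)

    def test_affine_invariance(self, rng):
        a, b = rng.normal(1, 0.3, 50), rng.normal(0.5, 0.2, 50)
        for c, k in [(2.0, 0.0), (0.5, 3.0), (10.0, -1.0)]:
            assert dprime(c * a + k, c * b + k) == pytest.approx(dprime(a, b))

    def test_matches_independent_oracle_on_random_instances(self, rng):
        """1000 random small groups agree with a direct formula evaluation."""
        for _ in range(1000):
            na, nb = rng.integers(2, 12, 2)
            a, b = rng.normal(0, 1, na), rng.normal(0.3, 1.2, nb)
            # oracle: plain sums, no numpy statistics helpers
            ma = sum(a) / na
            mb = sum(b) / nb
            va = sum((x - ma) ** 2 for x in a) / (na - 1)
            vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
            expected = (ma - mb) / np.sqrt(0.5 * (va + vb))
            assert dprime(a, b) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_unequal_constants_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert dprime([1.0, 1.0], [0.0, 0.0]) == np.inf


class TestLightDose:
    def test_head_fixed_intensity(self):
        """200 mW over a 6.5 mm circle gives ~6 mW/mm^2."""
        res = light_dose(DoseSpec(power_mw=200, aperture_diameter_mm=6.5))
        assert res.intensity_mw_per_mm2 == pytest.approx(6.03, abs=0.01)

    def test_freely_moving_intensity(self):
        """485 mW over a 15.25 cm circle gives ~2.65 mW/cm^2."""
        res = light_dose(DoseSpec(power_mw=485, aperture_diameter_mm=152.5))
        assert res.intensity_mw_per_cm2 == pytest.approx(2.655, abs=0.01)

    def test_zero_cycles_zero_dose(self):
        res = light_dose(DoseSpec(100, 5.0, 1.0, 0))
        assert res.cumulative_dose == 0.0

    def test_dose_additivity(self):
        one = light_dose(DoseSpec(100, 5.0, 1.0, 1)).cumulative_dose
        many = light_dose(DoseSpec(100, 5.0, 1.0, 17)).cumulative_dose
        longer = light_dose(DoseSpec(100, 5.0, 17.0, 1)).cumulative_dose
        assert many == pytest.approx(17 * one)
        assert longer == pytest.approx(17 * one)

    def test_cycle_bookkeeping(self):
        assert cycles_for_dose(1150, 6.0) == 192

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            DoseSpec(power_mw=-1, aperture_diameter_mm=5)


class TestDecayFit:
    def test_exact_exponential_points(self):
        res = ExponentialDecayModel([0, 1, 2], [1.0, 0.5, 0.25]).fit()
        assert res.half_life == pytest.approx(1.0, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0)
        assert res.predict(res.half_life) == pytest.approx(0.5, rel=1e-6)

    def test_fixed_point_self_consistency(self):
        """Refitting data generated from a fitted model returns the same
        half-life (noiseless fixed point)."""
        days = np.array([0, 1, 2, 3, 5, 7, 10, 15], dtype=float)
        res1 = ExponentialDecayModel(days, 2.0 ** (-days / 1.3)).fit()
        res2 = ExponentialDecayModel(days, res1.predict(days)).fit()
        assert res2.half_life == pytest.approx(res1.half_life, rel=1e-8)

    def test_default_cohort_recovery_within_10pct(self):
        cohort = simulate_decay_cohort(DecayCohortSpec(seed=12))
        res = ExponentialDecayModel.from_cohort(cohort).fit()
        assert res.half_life == pytest.approx(1.04, rel=0.10)

    def test_non_decreasing_data_warns(self):
        with pytest.warns(UserWarning, match="non-decreasing"):
            ExponentialDecayModel([0, 1, 2], [1.0, 1.1, 1.2]).fit()

    def test_free_offset_option(self):
        days = np.array([0, 1, 2, 3, 5, 7], dtype=float)
        y = 0.9 * 2.0 ** (-days / 1.5) + 0.1
        res = ExponentialDecayModel(days, y).fit(free_amplitude=True, free_offset=True)
        assert res.params["offset"] == pytest.approx(0.1, abs=1e-5)
        assert res.half_life == pytest.approx(1.5, rel=1e-4)


class TestDoseResponse:
    def test_pure_cubic_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = DoseResponseModel(x, x**3, degree=3).fit()
        np.testing.assert_allclose(res.coef, [0, 0, 0, 1], atol=1e-8)
        assert res.r_squared == pytest.approx(1.0)

    def test_degree_one_interpolates_two_points(self):
        res = DoseResponseModel([0.0, 2.0], [1.0, 5.0], degree=1).fit()
        np.testing.assert_allclose(res.coef, [1.0, 2.0], atol=1e-10)

    def test_argmax_of_constructed_concave_curve(self):
        """A concave sensitivity curve peaked at dose 300 is located to
        within the grid spacing."""
        doses = np.array([50, 100, 150, 200, 300, 450, 600], dtype=float)
        y = -((doses - 300.0) ** 2)  # peak exactly at 300
        res = DoseResponseModel(doses, y, degree=2).fit(grid_spacing=1.0)
        assert abs(res.optimum_dose - 300.0) <= 1.0

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            DoseResponseModel([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], degree=3).fit()


class TestIntegrateGratingResponse:
    def test_constant_trace_integrates_to_zero(self):
        proto = StimulusProtocol(frame_rate=30)
        trace, epochs = simulate_grating_traces(proto, response_amplitude=0.0,
                                                baseline=5.0)
        with pytest.warns(UserWarning, match="pre-stimulus"):
            total, per_epoch = integrate_grating_response(trace, epochs, 30.0)
        assert total == pytest.approx(0.0, abs=1e-9)
        # the first grating starts at frame 0: no 2-s baseline before it
        assert len(per_epoch) == proto.n_epochs - 1

    def test_step_response_value(self):
        """A step from c to 2c during the stimulus integrates to 60c at 30 fps."""
        c = 2.0
        fr = 30.0
        n_base, n_resp = int(2 * fr), int(4 * fr)
        trace = np.concatenate([np.full(n_base, c), np.full(n_resp, 2 * c),
                                np.full(60, c)])
        epochs = pd.DataFrame({"epoch": [0], "onset_frame": [n_base],
                               "offset_frame": [n_base + n_resp]})
        total, _ = integrate_grating_response(trace, epochs, fr)
        assert total == pytest.approx(60 * c)

    def test_monotone_in_response_amplitude(self):
        """Integrated responses across 40 appearances rank with the generated
        amplitude even under noise."""
        proto = StimulusProtocol(frame_rate=15)
        totals = []
        for i, amp in enumerate(np.linspace(0.0, 2.0, 6)):
            trace, epochs = simulate_grating_traces(proto, response_amplitude=amp,
                                                    baseline=1.0, noise_sd=0.2, seed=i)
            with pytest.warns(UserWarning, match="pre-stimulus"):
                total, _ = integrate_grating_response(trace, epochs, proto.frame_rate)
            totals.append(total)
        assert np.all(np.diff(totals) > 0)
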