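"""Model fitting, likelihood-ratio tests, Bayes factors, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from aperture3d.estimators import NoiseParams
from aperture3d.fitting import (
    FitResult,
    SchemaError,
    bayes_factor,
    bootstrap_fit,
    fit_model,
    lr_test,
    mirror_collapse,
    noise_difference_test,
    probe_from_direction,
    scale_probe_disparity,
    triangulate_probe,
    validate_trial_table,
)
from aperture3d.synthetic import (
    GenerativeObserver,
    exp1_design,
    exp2_design,
    simulate_observer,
)

# chi-square statistics and Bayes factors reported for the five observers
# in each experiment (n = 14 fitted conditions in both)
PRINTED_CHI2_BF = [
    (1.89, 0.69),
    (8.27, 16.7),
    (5.08, 3.4),
    (3.28, 1.4),
    (3.37, 1.4),
    (6.65, 7.4),
    (5.8, 4.9),
    (6.6, 7.3),
    (6.1, 5.5),
    (6.9, 8.5),
]


class TestBayesFactor:
    def test_evidence_balance_point(self):
        assert bayes_factor(np.log(14), 14) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("chi2,bf", PRINTED_CHI2_BF)
    def test_reported_pairs(self, chi2, bf):
        assert bayes_factor(chi2, 14) == pytest.approx(bf, abs=0.15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes_factor(-1.0, 14)
        with pytest.raises(ValueError):
            bayes_factor(1.0, 1)


def _fit_result(model, loglik, rss=1.0, fingerprint="x", n_cond=14):
    sm = 5.0 if model == "BVN1" else 8.0
    return FitResult(
        model_tag=model,
        sigma_m_pct=sm,
        sigma_d_pct=5.0,
        log_likelihood=loglik,
        rss=rss,
        n_trials=280,
        n_conditions=n_cond,
        n_residuals=560,
        converged=True,
        n_starts=1,
        data_fingerprint=fingerprint,
    )


class TestLRTest:
    def test_identical_fits(self):
        c = lr_test(_fit_result("BVN1", -100.0), _fit_result("BVN2", -100.0))
        assert c.chi2 == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_reported_chi2_to_p(self):
        c = lr_test(_fit_result("BVN1", -104.135), _fit_result("BVN2", -100.0))
        assert c.chi2 == pytest.approx(8.27, abs=1e-9)
        assert c.p_value == pytest.approx(0.004, abs=5e-4)

    def test_p_matches_quadrature_oracle(self):
        chi2 = 5.08
        c = lr_test(_fit_result("BVN1", -100.0 - chi2 / 2), _fit_result("BVN2", -100.0))
        tail, _ = integrate.quad(lambda x: stats.chi2.pdf(x, 1), chi2, np.inf)
        assert c.p_value == pytest.approx(tail, rel=1e-8)

    def test_different_data_raise(self):
        with pytest.raises(ValueError):
            lr_test(
                _fit_result("BVN1", -100.0, fingerprint="a"),
                _fit_result("BVN2", -99.0, fingerprint="b"),
            )


class TestFitModel:
    def test_noise_free_self_consistency(self, geom):
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.04, 0.02), response_noise_sd_deg=0.0, n_reps=1, seed=0
        )
        trials = simulate_observer(exp1_design(), obs, geom)
        fit = fit_model(trials, "BVN2", geom)
        assert fit.sigma_m_pct == pytest.approx(4.0, rel=1e-3)
        assert fit.sigma_d_pct == pytest.approx(2.0, rel=1e-3)
        assert fit.rss < 1e-10

    def test_optimum_beats_exhaustive_grid(self, geom):
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.06, 0.03), response_noise_sd_deg=2.0, n_reps=5, seed=42
        )
        trials = simulate_observer(exp1_design(), obs, geom)
        fit = fit_model(trials, "BVN2", geom)
        from aperture3d.fitting import _prepare, _rss

        prepared = _prepare(trials, geom)
        grid_m = np.exp(np.linspace(np.log(0.001), np.log(0.5), 51))
        grid_d = np.exp(np.linspace(np.log(0.001), np.log(10.0), 51))
        best_grid = min(
            _rss(*prepared, NoiseParams.bvn2(float(a), float(b)))
            for a in grid_m
            for b in grid_d
        )
        assert fit.rss <= best_grid + 1e-9

    def test_nesting_loglik(self, geom):
        """BVN2 can emulate BVN1 (depth pathway down-weighted to the search
        bound), so its maximized likelihood is never materially lower."""
        obs = GenerativeObserver(
            noise=NoiseParams.bvn1(0.05), response_noise_sd_deg=3.0, n_reps=10, seed=9
        )
        trials = simulate_observer(exp1_design(), obs, geom)
        f1 = fit_model(trials, "BVN1", geom)
        f2 = fit_model(trials, "BVN2", geom)
        assert f2.log_likelihood >= f1.log_likelihood - 1e-6

    def test_too_few_conditions(self, geom):
        obs = GenerativeObserver(noise=NoiseParams.bvn1(0.05), n_reps=3, seed=1)
        trials = simulate_observer(exp1_design()[:1], obs, geom)
        with pytest.raises(ValueError):
            fit_model(trials, "BVN1", geom)


class TestSchema:
    def test_missing_column(self, geom):
        df = pd.DataFrame({"observer": ["a"], "experiment": [1]})
        with pytest.raises(SchemaError, match="missing columns"):
            validate_trial_table(df)

    def test_non_numeric_angle_names_row(self, geom):
        obs = GenerativeObserver(noise=NoiseParams.bvn1(0.05), n_reps=1, seed=1)
        trials = simulate_observer(exp1_design(), obs, geom)
        trials.loc[3, "latitude_deg"] = "oops"
        with pytest.raises(SchemaError, match="row 3"):
            validate_trial_table(trials)

    def test_out_of_range_angle(self, geom):
        obs = GenerativeObserver(noise=NoiseParams.bvn1(0.05), n_reps=1, seed=1)
        trials = simulate_observer(exp1_design(), obs, geom)
        trials.loc[5, "latitude_deg"] = 91.0
        with pytest.raises(SchemaError, match="range"):
            validate_trial_table(trials)


class TestProbeScaling:
    def test_factor_one_is_identity_on_disparity(self, geom):
        x, y, d = probe_from_direction(30.0, 10.0, 2.0, geom)
        p = triangulate_probe(x, y, d, geom)
        from aperture3d.geometry import to_spherical

        ang = to_spherical(p)
        assert ang.longitude_deg == pytest.approx(30.0, abs=1e-9)
        assert ang.latitude_deg == pytest.approx(10.0, abs=1e-9)

    def test_scale_round_trip(self, geom):
        """Dividing stored disparities by the factor and re-scaling by it
        recovers the original direction angles."""
        rng = np.random.default_rng(2)
        rows = []
        want = []
        for k in range(12):
            lon = float(rng.uniform(-60, 60))
            lat = float(rng.uniform(-40, 40))
            x, y, d = probe_from_direction(lon, lat, 2.0, geom)
            rows.append(
                {
                    "observer": "s1",
                    "experiment": 1,
                    "tilt_deg": 0.0,
                    "orientation_disparity_deg": 0.0,
                    "iovd_sign": 1,
                    "rep": k,
                    "probe_x_cm": x,
                    "probe_y_cm": y,
                    "probe_disparity_cm": d / 0.6,  # raw, pre-scaling setting
                }
            )
            want.append((lon, lat))
        out = scale_probe_disparity(pd.DataFrame(rows), 0.6, geom)
        assert np.allclose(out["longitude_deg"], [w[0] for w in want], atol=1e-9)
        assert np.allclose(out["latitude_deg"], [w[1] for w in want], atol=1e-9)

    def test_zero_disparity_gives_zero_longitude(self, geom):
        p = triangulate_probe(1.0, 0.5, 0.0, geom)
        from aperture3d.geometry import to_spherical

        assert to_spherical(p).longitude_deg == pytest.approx(0.0, abs=1e-12)

    def test_point_behind_eyes_raises(self, geom):
        with pytest.raises(ValueError):
            triangulate_probe(0.0, 0.0, -geom.ipd_cm, geom)


class TestNoiseDifference:
    def test_textbook_formula(self):
        res = noise_difference_test([(d + 1, 1.0) for d in (1, 2, 3, 4, 5)])
        diffs = np.array([1, 2, 3, 4, 5], dtype=float)
        se = diffs.std(ddof=1) / np.sqrt(5)
        assert res.mean_difference_pct == pytest.approx(3.0)
        assert res.t == pytest.approx(3.0 / se, rel=1e-12)
        assert res.df == 4
        tcrit = stats.t.ppf(0.975, 4)
        assert res.ci95[0] == pytest.approx(3.0 - tcrit * se, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            noise_difference_test([(3.0, 1.0)] * 5)

    def test_too_few_observers(self):
        with pytest.raises(ValueError):
            noise_difference_test([(3.0, 1.0)])


class TestBootstrap:
    def test_degenerate_single_replicate_equals_point(self, geom):
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.05, 0.02), response_noise_sd_deg=2.0, n_reps=4, seed=3
        )
        trials = simulate_observer(exp1_design(), obs, geom)
        res = bootstrap_fit(trials, 1, seed=0, geometry=geom, resample=False)
        assert res.replicates.loc[0, "sigma_m_pct"] == pytest.approx(
            res.point.sigma_m_pct, rel=1e-6
        )
        assert res.replicates.loc[0, "sigma_d_pct"] == pytest.approx(
            res.point.sigma_d_pct, rel=1e-6
        )

    def test_seed_determinism(self, geom):
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.05, 0.02), response_noise_sd_deg=3.0, n_reps=5, seed=4
        )
        trials = simulate_observer(exp1_design(), obs, geom)
        a = bootstrap_fit(trials, 15, seed=11, geometry=geom)
        b = bootstrap_fit(trials, 15, seed=11, geometry=geom)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_detects_motion_depth_gap(self, geom):
        """Generator with sigma_m twice sigma_d: the bootstrap difference
        distribution should lie almost entirely above zero."""
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.04, 0.02), response_noise_sd_deg=3.0, n_reps=20, seed=21
        )
        trials = simulate_observer(exp1_design() + exp2_design(), obs, geom)
        res = bootstrap_fit(trials, 80, seed=5, geometry=geom)
        frac = np.mean(res.replicates["sigma_m_pct"] > res.replicates["sigma_d_pct"])
        assert frac > 0.95


class TestMirrorCollapse:
    def test_collapses_to_14_conditions(self, geom):
        obs = GenerativeObserver(noise=NoiseParams.bvn2(0.04, 0.02), n_reps=2, seed=6)
        trials = simulate_observer(exp2_design(), obs, geom)
        collapsed = mirror_collapse(trials)
        keys = collapsed[["tilt_deg", "orientation_disparity_deg", "iovd_sign"]]
        assert keys.drop_duplicates().shape[0] == 14
        assert (collapsed["tilt_deg"] <= 90).all()

    def test_fit_invariant_under_collapse(self, geom):
        """A symmetric generator yields the same fitted ratios whether the
        28 oblique conditions are fitted raw or mirror-collapsed."""
        obs = GenerativeObserver(
            noise=NoiseParams.bvn2(0.05, 0.025), response_noise_sd_deg=0.0, n_reps=1, seed=7
        )
        trials = simulate_observer(exp2_design(), obs, geom)
        f_raw = fit_model(trials, "BVN2", geom)
        f_col = fit_model(mirror_collapse(trials), "BVN2", geom)
        assert f_col.sigma_m_pct == pytest.approx(f_raw.sigma_m_pct, rel=1e-4)
        assert f_col.sigma_d_pct == pytest.approx(f_raw.sigma_d_pct, rel=1e-4)
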