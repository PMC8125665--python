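import numpy as np
import pytest

from csfext import (
    ComponentTruth,
    FractionationCondition,
    IdentifiabilityError,
    ExtractionError,
    SimulationConfig,
    SolubilizationDataset,
    build_design,
    fit_all_variants,
    fit_linearized,
    generate_design,
    nls_oracle,
    simulate_alpha,
)


def make_dataset(conds, alphas, **kw):
    return SolubilizationDataset.from_records(conds, alphas, **kw)


def grid_conditions(Ts=(80, 90, 99, 105), wts=(60, 70, 80, 90), hs=(0.25, 0.5, 1, 1.5)):
    cfg = SimulationConfig(
        temperature_grid_c=Ts, fa_wt_percent_grid=wts, time_h_grid=hs
    )
    return generate_design(cfg)


class TestBuildDesign:
    def test_single_temperature_unidentifiable(self):
        conds = [
            FractionationCondition.from_lab_units(90, wt, h)
            for wt in (60, 70, 80) for h in (0.5, 1.0)
        ]
        ds = make_dataset(conds, np.linspace(0.3, 0.8, len(conds)))
        with pytest.raises(IdentifiabilityError, match="temperature"):
            build_design(ds, "arrhenius")

    def test_l16_design_matrix(self, l16_conds):
        ds = make_dataset(l16_conds, np.linspace(0.3, 0.9, 16))
        y, X = build_design(ds, "arrhenius", t_ref_c=70.0)
        assert X.shape == (16, 3) and y.shape == (16,)
        lnt = sorted(set(np.round(X[:, 2], 12)))
        expected = sorted(np.round(np.log([15.0, 30.0, 60.0, 90.0]), 12))
        assert lnt == expected
        assert X[:, 0].min() == 10.0 and X[:, 0].max() == 35.0

    def test_collinear_concentration_and_time(self):
        # two FA levels always paired with the same two times: ln C and ln t
        # carry the same one-dimensional information
        conds = [
            FractionationCondition.from_lab_units(T, wt, h)
            for T in (80, 90, 99, 105)
            for wt, h in ((60, 0.25), (90, 1.0))
        ]
        ds = make_dataset(conds, np.linspace(0.2, 0.9, len(conds)))
        with pytest.raises(IdentifiabilityError, match="rank deficient"):
            build_design(ds, "arrhenius")

    def test_noiseless_response_exactly_linear(self, noiseless_dataset, pooled_truth):
        y, X = build_design(noiseless_dataset, "arrhenius", t_ref_c=70.0)
        beta = np.array(
            [
                pooled_truth.slope / pooled_truth.omega,
                pooled_truth.slope * pooled_truth.m,
                pooled_truth.slope,
            ]
        )
        resid = y - (X @ beta + pooled_truth.intercept)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_too_few_rows_rejected(self, l16_conds):
        with pytest.raises(ValueError, match="at least 5"):
            make_dataset(l16_conds[:4], [0.3, 0.4, 0.5, 0.6])


class TestFitLinearized:
    @pytest.mark.parametrize("family", ["arrhenius", "logistic"])
    def test_noiseless_recovery(self, family):
        truth = ComponentTruth(family, 14.54, 12.10, 0.1446, -5.5595)
        cfg = SimulationConfig(truth={"pooled": truth}, noise_sigma=0.0, seed=0)
        ds = simulate_alpha(generate_design(cfg), cfg)
        fit = fit_linearized(ds, family, t_ref_c=70.0)
        assert fit.constants.omega == pytest.approx(14.54, abs=1e-8)
        assert fit.constants.m == pytest.approx(12.10, abs=1e-8)
        assert fit.model.slope == pytest.approx(0.1446, abs=1e-8)
        assert fit.model.intercept == pytest.approx(-5.5595, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_beta_to_parameter_extraction_identities(self, noiseless_dataset):
        fit = fit_linearized(noiseless_dataset, "arrhenius")
        b0, b1, b2, b3 = fit.beta
        assert fit.constants.omega == pytest.approx(b3 / b1, rel=1e-12)
        assert fit.constants.m == pytest.approx(b2 / b3, rel=1e-12)
        assert fit.model.slope == b3 and fit.model.intercept == b0

    def test_noisy_fit_diagnostics(self, pooled_truth):
        cfg = SimulationConfig(
            truth={"pooled": pooled_truth},
            time_h_grid=(0.25, 0.5, 1.0, 1.5, 2.0),
            noise_sigma=0.15,
            seed=42,
        )
        ds = simulate_alpha(generate_design(cfg), cfg)
        fit = fit_linearized(ds, "arrhenius")
        assert fit.n == 80
        # band verified by repeated simulation at these exact conditions
        assert 0.75 < fit.r_squared < 0.95
        assert fit.p_value < 1e-6
        assert fit.f_statistic > 0
        # F consistent with its R-squared definition, k = 3
        k, n = 3, fit.n
        f_from_r2 = (fit.r_squared / k) / ((1 - fit.r_squared) / (n - k - 1))
        assert fit.f_statistic == pytest.approx(f_from_r2, rel=1e-9)

    def test_refit_reproduces_fitresult(self, noiseless_dataset):
        """Data simulated from a fit reproduces that fit (noiseless)."""
        fit = fit_linearized(noiseless_dataset, "arrhenius")
        truth = ComponentTruth(
            "arrhenius", fit.constants.omega, fit.constants.m,
            fit.model.slope, fit.model.intercept,
        )
        cfg = SimulationConfig(truth={"again": truth}, noise_sigma=0.0, seed=9)
        ds2 = simulate_alpha(generate_design(cfg), cfg)
        fit2 = fit_linearized(ds2, "arrhenius")
        assert fit2.constants.omega == pytest.approx(fit.constants.omega, abs=1e-8)
        assert fit2.constants.m == pytest.approx(fit.constants.m, abs=1e-8)
        assert fit2.model.slope == pytest.approx(fit.model.slope, abs=1e-8)
        assert fit2.model.intercept == pytest.approx(fit.model.intercept, abs=1e-8)

    def test_t_ref_shift_equivariance(self, noiseless_dataset):
        """Shifting T_ref leaves omega, m, slope; intercept moves by slope*d/omega."""
        f70 = fit_linearized(noiseless_dataset, "arrhenius", t_ref_c=70.0)
        f85 = fit_linearized(noiseless_dataset, "arrhenius", t_ref_c=85.0)
        assert f85.constants.omega == pytest.approx(f70.constants.omega, rel=1e-9)
        assert f85.constants.m == pytest.approx(f70.constants.m, rel=1e-9)
        assert f85.model.slope == pytest.approx(f70.model.slope, rel=1e-9)
        shift = f70.model.slope * 15.0 / f70.constants.omega
        assert f85.model.intercept == pytest.approx(
            f70.model.intercept + shift, rel=1e-9
        )

    def test_r_squared_invariant_to_affine_predictor_changes(self, pooled_truth):
        cfg = SimulationConfig(truth={"pooled": pooled_truth}, noise_sigma=0.1, seed=3)
        ds = simulate_alpha(generate_design(cfg), cfg)
        r2_ref = fit_linearized(ds, "arrhenius", t_ref_c=70.0).r_squared
        assert fit_linearized(ds, "arrhenius", t_ref_c=95.0).r_squared == pytest.approx(
            r2_ref, rel=1e-10
        )

    def test_constant_response_extraction_error(self, l16_conds):
        ds = make_dataset(l16_conds, np.full(16, 0.5))
        with pytest.raises(ExtractionError):
            fit_linearized(ds, "arrhenius")


class TestFitAllVariants:
    def test_identical_datasets_identical_fits(self, noiseless_dataset):
        fits, report = fit_all_variants(
            {"a": noiseless_dataset, "b": noiseless_dataset}, "arrhenius"
        )
        assert fits["a"].constants == fits["b"].constants
        assert fits["a"].model == fits["b"].model
        assert set(report["variant"]) == {"a", "b"}

    def test_failed_variant_reported_not_fatal(self, noiseless_dataset, l16_conds):
        saturated = make_dataset(l16_conds, np.ones(16))
        with pytest.warns(UserWarning, match="clipped"):
            fits, report = fit_all_variants(
                {"ok": noiseless_dataset, "saturated": saturated}, "arrhenius"
            )
        assert "ok" in fits and "saturated" not in fits
        row = report[report["variant"] == "saturated"].iloc[0]
        assert row["error"] != ""

    def test_report_ranked_by_r_squared(self, pooled_truth):
        quiet = SimulationConfig(truth={"x": pooled_truth}, noise_sigma=0.05, seed=5)
        loud = SimulationConfig(truth={"x": pooled_truth}, noise_sigma=0.3, seed=5)
        ds_q = simulate_alpha(generate_design(quiet), quiet)
        ds_l = simulate_alpha(generate_design(loud), loud)
        _, report = fit_all_variants({"quiet": ds_q, "loud": ds_l}, "arrhenius")
        assert report.iloc[0]["variant"] == "quiet"
        assert report["r_squared"].is_monotonic_decreasing


class TestNlsOracle:
    @pytest.mark.parametrize("family", ["arrhenius", "logistic"])
    def test_agrees_with_linearized_on_noiseless_data(self, family):
        truth = ComponentTruth(family, 14.54, 12.10, 0.1446, -5.5595)
        cfg = SimulationConfig(truth={"pooled": truth}, noise_sigma=0.0, seed=0)
        ds = simulate_alpha(generate_design(cfg), cfg)
        lin = fit_linearized(ds, family)
        nls = nls_oracle(ds, family, init=lin)
        assert nls.constants.omega == pytest.approx(lin.constants.omega, abs=1e-6)
        assert nls.constants.m == pytest.approx(lin.constants.m, abs=1e-6)
        assert nls.model.slope == pytest.approx(lin.model.slope, abs=1e-6)
        assert nls.model.intercept == pytest.approx(lin.model.intercept, abs=1e-6)

    def test_init_at_truth_stays_at_truth(self, noiseless_dataset):
        lin = fit_linearized(noiseless_dataset, "arrhenius")
        nls = nls_oracle(noiseless_dataset, "arrhenius", init=lin)
        assert np.max(np.abs(nls.residuals)) < 1e-8

    def test_heavy_noise_both_estimators_finite(self, pooled_truth):
        cfg = SimulationConfig(truth={"pooled": pooled_truth}, noise_sigma=1.0, seed=11)
        ds = simulate_alpha(generate_design(cfg), cfg)
        lin = fit_linearized(ds, "arrhenius")
        nls = nls_oracle(ds, "arrhenius", init=lin)
        for fit in (lin, nls):
            assert np.isfinite(fit.constants.omega)
            assert np.isfinite(fit.constants.m)
            assert np.isfinite(fit.model.slope)
            assert np.isfinite(fit.model.intercept)
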