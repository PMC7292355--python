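"""Cross-species prediction equations: design, OLS, selection, prediction."""

import numpy as np
import pytest

from dialyzability import (
    DialyzabilityModel,
    DrugRecord,
    RangeConvention,
    RegressionFit,
    build_design,
    fit_ols,
    load_fixture_tables,
    predict_dd_human,
    records_from_dataframe,
    select_best_model,
    unbound_ratio,
    vd_ratio,
)


def make_record(name="X", removal_4h=30.0, dd=40.0, pbr_rat=20.0, pbr_human=10.0,
                vd_rat=1.0, vd_human=1.0):
    return DrugRecord(
        name=name, removal_2h_rat=removal_4h / 2, removal_4h_rat=removal_4h,
        dd_human=dd, dd_human_range=(dd, dd), pbr_rat=pbr_rat, pbr_human=pbr_human,
        vd_rat=vd_rat, vd_human=vd_human, vd_human_range=(vd_human, vd_human),
    )


class TestSpeciesRatios:
    def test_unbound_ratio_doripenem(self):
        rec = make_record(pbr_rat=26.1, pbr_human=2.5)
        assert unbound_ratio(rec) == pytest.approx(97.5 / 73.9, rel=1e-12)

    def test_unbound_ratio_identity(self):
        assert unbound_ratio(make_record(pbr_rat=35.0, pbr_human=35.0)) == 1.0

    def test_unbound_ratio_aprindine(self):
        rec = make_record(pbr_rat=93.3, pbr_human=91.2)
        assert unbound_ratio(rec) == pytest.approx(8.8 / 6.7, rel=1e-12)

    def test_fully_bound_rat_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            unbound_ratio(make_record(pbr_rat=100.0, pbr_human=50.0))

    def test_vd_ratio_acetaminophen(self):
        rec = make_record(vd_rat=2.21, vd_human=3.18)
        assert vd_ratio(rec) == pytest.approx(3.18 / 2.21, rel=1e-12)

    def test_vd_ratio_aprindine_upper_bound(self):
        records = {r.name: r for r in load_fixture_tables(RangeConvention(vd="upper"))}
        assert vd_ratio(records["AP"]) == pytest.approx(10.5 / 54.51, rel=1e-12)


class TestDesign:
    def test_eq1_design_is_the_rat_4h_column(self, drug_records):
        y, X = build_design(drug_records, 1)
        assert X[:, 0] == pytest.approx([r.removal_4h_rat for r in drug_records])
        assert y == pytest.approx([r.dd_human for r in drug_records])

    def test_eq2_predictor_for_doripenem(self, drug_records):
        rec = {r.name: r for r in drug_records}["DRPM"]
        _, X = build_design([rec] * 6, 2)  # arity check only needs >= 5 rows
        assert X[0, 0] == pytest.approx(29.6 * 97.5 / 73.9, rel=1e-12)

    def test_zero_removal_contributes_zero(self, drug_records):
        rec = {r.name: r for r in drug_records}["AP"]
        for eq in (1, 2, 3, 4):
            _, X = build_design([rec] * 6, eq)
            assert X[0, 0] == 0.0

    def test_too_few_drugs_rejected(self, drug_records):
        with pytest.raises(ValueError, match="at least"):
            build_design(drug_records[:3], 1)
        with pytest.raises(ValueError, match="at least"):
            build_design(drug_records[:4], 3)

    def test_missing_field_names_drug_and_column(self, drug_records):
        import pandas as pd
        from dialyzability.crossspecies import records_from_dataframe

        df = pd.DataFrame(
            {
                "drug": ["A"], "removal_2h": [1.0], "removal_4h": [2.0],
                "dd_human_lo": [3.0], "dd_human_hi": [3.0], "pbr_rat": [np.nan],
                "pbr_human": [1.0], "vd_rat": [1.0], "vd_human_lo": [1.0],
                "vd_human_hi": [1.0],
            }
        )
        with pytest.raises(ValueError, match="A.*pbr_rat"):
            records_from_dataframe(df)


class TestOls:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_ols(2.0 + 3.0 * x, x, equation_id=1)
        assert fit.a0 == pytest.approx(2.0, abs=1e-10)
        assert fit.a1 == pytest.approx(3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_singular_design_rejected(self):
        X = np.column_stack([np.arange(6.0), 2.0 * np.arange(6.0)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(np.arange(6.0), X, equation_id=3)

    def test_matches_normal_equation_oracle_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 9)
            p = rng.integers(1, 3)
            if n <= p + 1:
                continue
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            design = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            fit = fit_ols(y, X, equation_id=1 if p == 1 else 3)
            assert np.allclose(fit.coefficients, beta, atol=1e-8)
            resid = y - design @ beta
            ss_res = resid @ resid
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - ss_res / ss_tot
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)
            assert fit.adj_r_squared == pytest.approx(adj, abs=1e-10)

    def test_adjusted_never_exceeds_raw_r_squared(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            X = rng.normal(size=(8, 2))
            y = rng.normal(size=8)
            fit = fit_ols(y, X, equation_id=3)
            assert fit.adj_r_squared <= fit.r_squared + 1e-12

    def test_parameter_recovery_within_three_standard_errors(self):
        # y = a0 + a1 x + N(0, sigma), n = 50: truth inside +-3 SE for
        # >= 95% of 200 seeds
        a0_true, a1_true, sigma, n = 5.0, 2.0, 1.0, 50
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.0, 10.0, size=n)
            y = a0_true + a1_true * x + rng.normal(0.0, sigma, size=n)
            fit = fit_ols(y, x, equation_id=1)
            se0, se1 = fit.coef_se[0], fit.coef_se[1]
            if abs(fit.a0 - a0_true) <= 3 * se0 and abs(fit.a1 - a1_true) <= 3 * se1:
                hits += 1
        assert hits >= 190


class TestFixtureRegression:
    def test_adjusted_r2_reproduces_reference(self, fitted_results):
        expected = {1: 0.812, 2: 0.936, 3: 0.749, 4: 0.751}
        for eq, ref in expected.items():
            assert fitted_results.fits[eq].adj_r_squared == pytest.approx(ref, abs=5e-3)

    def test_slopes_reproduce_reference(self, fitted_results):
        assert fitted_results.fits[1].a1 == pytest.approx(1.264, abs=5e-3)
        assert fitted_results.fits[2].a1 == pytest.approx(1.227, abs=5e-3)

    def test_overall_significance_eq1(self, fitted_results):
        assert fitted_results.fits[1].p_value == pytest.approx(0.009, abs=2e-3)

    def test_published_ordering_of_equations(self, fitted_results):
        adj = {eq: f.adj_r_squared for eq, f in fitted_results.fits.items()}
        assert adj[2] > adj[1] > adj[4] > adj[3]

    def test_protein_binding_adjusted_model_selected(self, fitted_results):
        assert fitted_results.selected_id == 2

    def test_summary_mentions_selection(self, fitted_results):
        text = fitted_results.summary()
        assert "Eq 2" in text and "adjusted r2" in text


class TestSelection:
    def _fit(self, eq, adj):
        return RegressionFit(equation_id=eq, a0=0, a1=1, a2=None, r_squared=adj,
                             adj_r_squared=adj, p_value=0.05, n=6)

    def test_reference_scenario_selects_eq2(self):
        fits = [self._fit(1, 0.812), self._fit(2, 0.936),
                self._fit(3, 0.749), self._fit(4, 0.751)]
        assert select_best_model(fits) == 2

    def test_single_fit(self):
        assert select_best_model([self._fit(3, 0.5)]) == 3

    def test_tie_breaks_to_lowest_id(self):
        assert select_best_model([self._fit(4, 0.9), self._fit(2, 0.9)]) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


class TestPrediction:
    def test_doripenem_lands_in_human_range(self, drug_records, fitted_results):
        rec = {r.name: r for r in drug_records}["DRPM"]
        pred = fitted_results.predict(rec, equation_id=2)
        assert 46.3 <= pred <= 56.1

    def test_zero_removal_predicts_intercept(self, fitted_results):
        rec = make_record(removal_4h=0.0)
        fit = fitted_results.fits[2]
        assert predict_dd_human(fit, rec) == pytest.approx(fit.a0)

    def test_fitted_value_identity(self, drug_records, fitted_results):
        # applying the fit to a fitted drug returns that drug's fitted value
        y, X = build_design(drug_records, 1)
        fit = fitted_results.fits[1]
        for rec, x in zip(drug_records, X[:, 0]):
            assert predict_dd_human(fit, rec) == pytest.approx(
                fit.a0 + fit.a1 * x, rel=1e-12
            )

    def test_clipping_bounds_output(self, fitted_results):
        rec = make_record(removal_4h=100.0)
        raw = fitted_results.predict(rec, equation_id=1)
        clipped = fitted_results.predict(rec, equation_id=1, clip=True)
        assert raw > 100.0 and clipped == 100.0


class TestFixtureTable:
    def test_six_drugs(self, drug_records):
        assert len(drug_records) == 6
        assert {r.name for r in drug_records} == {"AMK", "AP", "VCM", "DRPM", "VPA", "APAP"}

    def test_aprindine_not_detected_in_dialysate(self, drug_records):
        ap = {r.name: r for r in drug_records}["AP"]
        assert ap.removal_2h_rat == 0.0
        assert ap.removal_4h_rat == 0.0
        assert ap.dd_human == 0.0

    def test_vancomycin_upper_bound_resolution(self, drug_records):
        vcm = {r.name: r for r in drug_records}["VCM"]
        assert vcm.dd_human == 39.5
        assert vcm.dd_human_range == (20.8, 39.5)

    def test_convention_changes_resolution(self):
        mid = {r.name: r for r in load_fixture_tables(RangeConvention(dd="mid"))}
        assert mid["VCM"].dd_human == pytest.approx((20.8 + 39.5) / 2)

    def test_duplicate_drugs_rejected(self, drug_records):
        with pytest.raises(ValueError, match="duplicate"):
            DialyzabilityModel(list(drug_records) + [drug_records[0]])
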