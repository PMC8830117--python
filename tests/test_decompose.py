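"""Design matrix, outcome models and the Wagstaff-type decomposition."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_scenario, planted_education_scenario
from healthineq.decompose import (DesignMatrix, EstimationError, build_design,
                                  fit_logit_ame, fit_lpm, generalized_ci,
                                  percent_contributions,
                                  recover_planted_structure, wagstaff_decompose)
from healthineq.ranking import fractional_rank, ranks_for_table
from healthineq.simulate import generate_population
from healthineq.survey import DomainError, derive_indicators, validate_frame


def _design_from_columns(**cols) -> DesignMatrix:
    """Ad-hoc design for unit tests on the fitting/decomposition algebra."""
    X = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    n = len(X)
    means = pd.Series({c: X[c].mean() for c in X.columns})
    return DesignMatrix(X=X, reference_levels={}, means=means,
                        variable_of={c: c for c in X.columns})


class TestBuildDesign:
    def test_reference_record_has_all_dummies_zero(self, row_factory):
        table = validate_frame(row_factory([
            {"residence": "rural", "age_group": "15-24", "birth_order": "1",
             "education": "none", "caste": "Others", "media_exposure": "no"},
            {"residence": "urban"},
        ]))
        design = build_design(table)
        assert design.X.shape[1] == 12
        assert design.X.iloc[0].sum() == 0

    def test_non_reference_record_sets_one_dummy_per_variable(self, row_factory):
        table = validate_frame(row_factory([
            {"residence": "urban", "age_group": "35-49", "birth_order": "3+",
             "education": "higher", "caste": "OBC", "media_exposure": "yes"},
            {},
        ]))
        assert build_design(table).X.iloc[0].sum() == 6

    def test_weighted_means_recorded(self, row_factory):
        table = validate_frame(row_factory([
            {"residence": "urban"}, {"residence": "rural"},
        ]))
        assert build_design(table).means["urban"] == pytest.approx(0.5)

    def test_reference_override_swaps_omitted_level(self, row_factory):
        table = validate_frame(row_factory([{"residence": "urban"}, {}]))
        design = build_design(table, overrides={"residence": "urban"})
        assert "rural" in design.X.columns and "urban" not in design.X.columns

    def test_unknown_override_level_raises(self, row_factory):
        table = validate_frame(row_factory([{}]))
        with pytest.raises(DomainError):
            build_design(table, overrides={"residence": "suburban"})


class TestFitLpm:
    def test_perfect_fit_on_a_single_regressor(self):
        x = np.array([0, 0, 1, 1.0])
        design = _design_from_columns(x=x)
        res = fit_lpm(x, design, np.ones(4))
        assert res.beta["x"] == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.residuals, 0, atol=1e-12)

    def test_hand_least_squares_on_two_by_two(self):
        y = np.array([0, 1, 1, 1.0])
        design = _design_from_columns(x=[0, 0, 1, 1])
        res = fit_lpm(y, design, np.ones(4))
        assert res.beta["x"] == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.5)

    def test_weight_rescaling_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50).astype(float)
        design = _design_from_columns(a=rng.integers(0, 2, 50),
                                      b=rng.integers(0, 2, 50))
        w = rng.uniform(0.5, 2.0, 50)
        r1 = fit_lpm(y, design, w)
        r2 = fit_lpm(y, design, 3.7 * w)
        for k in r1.beta:
            assert r1.beta[k] == pytest.approx(r2.beta[k], abs=1e-10)

    def test_weighted_mean_residual_is_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80).astype(float)
        design = _design_from_columns(a=rng.integers(0, 2, 80))
        w = rng.uniform(0.5, 2.0, 80)
        res = fit_lpm(y, design, w)
        assert np.sum(w * res.residuals) / np.sum(w) == pytest.approx(0.0, abs=1e-10)

    def test_collinear_columns_are_named(self):
        x = np.array([0, 1, 0, 1.0])
        design = _design_from_columns(a=x, b=x)
        with pytest.raises(EstimationError, match="a|b"):
            fit_lpm(np.array([0, 1, 1, 0.0]), design, np.ones(4))

    def test_constant_column_dropped_with_notice(self, caplog):
        design = _design_from_columns(a=[0, 1, 0, 1], c=[0, 0, 0, 0])
        with caplog.at_level("WARNING"):
            res = fit_lpm(np.array([0, 1, 0, 1.0]), design, np.ones(4))
        assert "c" not in res.beta
        assert any("constant" in r.message for r in caplog.records)


class TestFitLogitAme:
    def test_no_association_gives_zero_ame(self):
        # balanced 2x2 with identical outcome rates in both x-cells
        x = np.repeat([0, 1], 10).astype(float)
        y = np.tile([1, 0], 10).astype(float)
        res = fit_logit_ame(y, _design_from_columns(x=x), np.ones(20))
        assert res.beta["x"] == pytest.approx(0.0, abs=1e-8)

    def test_saturated_ame_equals_difference_in_proportions(self):
        # cell rates 6/10 (x=1) vs 2/10 (x=0) -> AME 0.4
        x = np.repeat([0, 1], 10).astype(float)
        y = np.concatenate([np.r_[np.ones(2), np.zeros(8)],
                            np.r_[np.ones(6), np.zeros(4)]])
        res = fit_logit_ame(y, _design_from_columns(x=x), np.ones(20))
        assert res.model_kind == "logit_ame"
        assert res.beta["x"] == pytest.approx(0.4, abs=1e-8)

    def test_saturated_ame_with_weights_matches_weighted_cells(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 200).astype(float)
        y = rng.integers(0, 2, 200).astype(float)
        w = rng.uniform(0.5, 3.0, 200)
        res = fit_logit_ame(y, _design_from_columns(x=x), w)
        p1 = np.sum(w * y * x) / np.sum(w * x)
        p0 = np.sum(w * y * (1 - x)) / np.sum(w * (1 - x))
        assert res.beta["x"] == pytest.approx(p1 - p0, abs=1e-8)

    def test_ames_are_probability_differences(self):
        rng = np.random.default_rng(3)
        design = _design_from_columns(a=rng.integers(0, 2, 100),
                                      b=rng.integers(0, 2, 100))
        y = rng.integers(0, 2, 100).astype(float)
        res = fit_logit_ame(y, design, np.ones(100))
        for v in res.beta.values():
            assert -1 < v < 1

    def test_perfect_separation_falls_back_to_lpm(self, caplog):
        x = np.repeat([0, 1], 10).astype(float)
        with caplog.at_level("WARNING"):
            res = fit_logit_ame(x.copy(), _design_from_columns(x=x), np.ones(20))
        assert res.model_kind == "lpm"


class TestGeneralizedCI:
    def test_zero_residuals_give_zero(self):
        r = fractional_rank(np.arange(5.), np.ones(5))
        assert generalized_ci(np.zeros(5), r, np.ones(5)) == 0.0

    def test_outcome_as_residual_recovers_mu_times_c(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60).astype(float)
        y[0] = 1
        w = rng.uniform(0.5, 2.0, 60)
        r = fractional_rank(rng.normal(size=60), w)
        from healthineq.ranking import concentration_index, weighted_mean
        res = concentration_index(y, r, w)
        assert generalized_ci(y, r, w) == pytest.approx(res.mu * res.index, abs=1e-12)

    def test_rank_orthogonal_residuals_give_zero(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.5, 2.0, 40)
        r = fractional_rank(rng.normal(size=40), w)
        eps = rng.normal(size=40)
        wn = w / w.sum()
        rc = r - np.sum(wn * r)
        ec = eps - np.sum(wn * eps)
        # weighted Gram-Schmidt: remove the rank component from the residuals
        eps_orth = ec - (np.sum(wn * ec * rc) / np.sum(wn * rc * rc)) * rc
        assert generalized_ci(eps_orth, r, w) == pytest.approx(0.0, abs=1e-12)


class TestWagstaffDecompose:
    def test_perfect_fit_attributes_everything_to_the_regressor(self):
        y = np.array([0, 0, 1, 1.0])
        w = np.ones(4)
        r = fractional_rank(np.arange(4.), w)
        result = wagstaff_decompose(y, _design_from_columns(x=y), w, r, "lpm")
        assert result.explained == pytest.approx(result.total, abs=1e-12)
        assert result.residual == pytest.approx(0.0, abs=1e-12)

    def test_additivity_holds_with_weights_and_ties(self):
        rng = np.random.default_rng(6)
        n = 500
        scores = np.round(rng.normal(size=n), 1)  # plenty of ties
        w = rng.uniform(0.5, 3.0, n)
        r = fractional_rank(scores, w)
        y = rng.integers(0, 2, n).astype(float)
        design = _design_from_columns(a=rng.integers(0, 2, n),
                                      b=rng.integers(0, 2, n),
                                      c=rng.integers(0, 2, n))
        result = wagstaff_decompose(y, design, w, r, "lpm")
        assert result.explained + result.residual == pytest.approx(result.total,
                                                                   abs=1e-10)

    def test_rank_uncorrelated_regressor_contributes_nothing(self):
        w = np.ones(4)
        r = fractional_rank(np.arange(4.), w)  # 0.125 .375 .625 .875
        x = np.array([1, 0, 0, 1.0])           # symmetric about the median rank
        y = np.array([0, 1, 0, 1.0])
        result = wagstaff_decompose(y, _design_from_columns(x=x, z=y), w, r, "lpm")
        row = {r_.regressor: r_ for r_ in result.rows}["x"]
        assert row.ck == pytest.approx(0.0, abs=1e-12)
        assert row.contribution == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_invariant_to_regressor_order(self):
        rng = np.random.default_rng(7)
        n = 300
        w = rng.uniform(0.5, 2.0, n)
        r = fractional_rank(rng.normal(size=n), w)
        y = rng.integers(0, 2, n).astype(float)
        a, b = rng.integers(0, 2, n), rng.integers(0, 2, n)
        r1 = wagstaff_decompose(y, _design_from_columns(a=a, b=b), w, r, "lpm")
        r2 = wagstaff_decompose(y, _design_from_columns(b=b, a=a), w, r, "lpm")
        c1 = {row.regressor: row.contribution for row in r1.rows}
        c2 = {row.regressor: row.contribution for row in r2.rows}
        for k in c1:
            assert c1[k] == pytest.approx(c2[k], abs=1e-12)
        assert r1.explained == pytest.approx(r2.explained, abs=1e-12)

    def test_logit_ame_residual_closes_the_identity_by_construction(self):
        rng = np.random.default_rng(8)
        n = 400
        w = rng.uniform(0.5, 2.0, n)
        r = fractional_rank(rng.normal(size=n), w)
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.2 + 0.4 * x).astype(float)
        result = wagstaff_decompose(y, _design_from_columns(x=x), w, r, "logit_ame")
        assert result.model_kind == "logit_ame"
        assert result.explained + result.residual == pytest.approx(result.total,
                                                                   abs=1e-12)


class TestPercentContributions:
    def _result_with(self, contribs, total):
        from healthineq.decompose import DecompositionResult, DecompositionRow
        rows = [DecompositionRow(regressor=f"x{i}", beta=0, mean=0, ck=0,
                                 elasticity=0, contribution=c)
                for i, c in enumerate(contribs)]
        explained = sum(contribs)
        return DecompositionResult(rows=rows, explained=explained,
                                   residual=total - explained, total=total,
                                   model_kind="lpm", mu=0.5)

    def test_shares_of_total(self):
        pct = percent_contributions(self._result_with([0.05, 0.05], 0.2), "total")
        assert pct == {"x0": pytest.approx(25.0), "x1": pytest.approx(25.0)}

    def test_shares_of_explained(self):
        pct = percent_contributions(self._result_with([0.05, 0.05], 0.2), "explained")
        assert pct == {"x0": pytest.approx(50.0), "x1": pytest.approx(50.0)}

    def test_perfect_fit_single_regressor_is_one_hundred_percent(self):
        y = np.array([0, 0, 1, 1.0])
        w = np.ones(4)
        r = fractional_rank(np.arange(4.), w)
        result = wagstaff_decompose(y, _design_from_columns(x=y), w, r, "lpm")
        pct = percent_contributions(result, "total")
        assert pct["x"] == pytest.approx(100.0)

    def test_zero_denominator_yields_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pct = percent_contributions(self._result_with([0.0], 0.0), "total")
        assert np.isnan(pct["x0"])


class TestPlantedStructure:
    def test_zero_effect_scenario_has_no_inequality(self):
        from conftest import mc_se_of_ci
        report = recover_planted_structure(make_scenario(n=20000), seed=5)
        se = mc_se_of_ci(report["mu"], report["n"])
        assert abs(report["total"]) < 3 * se

    def test_pro_rich_education_dominates_the_explained_part(self):
        report = recover_planted_structure(planted_education_scenario(20000), seed=5)
        assert report["total"] > 0
        assert report["explained_share_by_variable"]["education"] >= 0.9

    def test_pro_poor_gradient_flips_the_sign(self):
        report = recover_planted_structure(
            planted_education_scenario(20000, direction=-1), seed=5)
        assert report["total"] < 0
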