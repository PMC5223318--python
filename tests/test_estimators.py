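"""Outcome model, counterfactual stack, contrasts, and the estimator variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gcomp
from gcomp import (
    EstimandRequest,
    ObservedData,
    OutcomeModelSpec,
    assign_potential_outcomes,
    build_counterfactual_stack,
    fit_outcome_model,
    gcompute,
    marginal_contrast,
    nonparametric_standardization,
    restriction_estimate,
    standardization_estimate,
)
from gcomp.estimators import _contrast
from gcomp.exceptions import (
    ConfigurationError,
    DegenerateOddsError,
    EstimationError,
    FitError,
    PositivityError,
    SeparationError,
)
from gcomp.synthetic import SyntheticConfig, generate_dataset

ATT_RD, ATU_RD, ATE_RD = 5 / 12, 3 / 8, 11 / 28
ATT_OR, ATU_OR, ATE_OR = 6.0, 5.0, 5.4


class TestOutcomeModelSpec:
    def test_default_terms_are_treatment_by_covariate_products(self):
        spec = OutcomeModelSpec.default(["age", "gender"])
        assert ("A", "age") in spec.product_terms
        assert ("A", "gender") in spec.product_terms
        assert ("A", "age", "gender") in spec.product_terms
        # no covariate-covariate products without the treatment
        assert ("age", "gender") not in spec.product_terms

    def test_saturated_includes_covariate_products(self):
        spec = OutcomeModelSpec.saturated(["age", "gender"])
        assert ("age", "gender") in spec.product_terms
        assert ("A", "age", "gender") in spec.product_terms

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            OutcomeModelSpec(product_terms=(("A", "C"), ("C", "A")))

    def test_unknown_variable_in_term_rejected(self, toy):
        spec = OutcomeModelSpec(product_terms=(("A", "Z"),))
        with pytest.raises(ConfigurationError, match="'Z'"):
            fit_outcome_model(toy, spec)


class TestFitOutcomeModel:
    def test_saturated_fit_reproduces_cell_means(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        cells = pd.DataFrame({"C": [1, 0, 1, 0]})
        p1 = model.predict(cells, treatment_value=1)
        p0 = model.predict(cells, treatment_value=0)
        np.testing.assert_allclose(p1[:2], [0.75, 0.50], atol=1e-9)
        np.testing.assert_allclose(p0[:2], [0.25, 0.25], atol=1e-9)

    def test_null_cells_give_zero_coefficients(self, null8):
        model = fit_outcome_model(null8, OutcomeModelSpec.saturated(null8.covariate_names))
        np.testing.assert_allclose(model.params, 0.0, atol=1e-8)

    def test_predictions_strictly_inside_unit_interval(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        p = model.predict(toy.covariates, 1)
        assert np.all(p > 0) and np.all(p < 1)

    def test_separation_raises(self):
        n = 20
        data = ObservedData(
            treatment=np.repeat([0, 1], n // 2),
            outcome=np.repeat([0, 1], n // 2),
            covariates=pd.DataFrame({"C": np.tile([0, 1], n // 2)}),
            unit_id=np.arange(n),
        )
        with pytest.raises(SeparationError):
            fit_outcome_model(data, OutcomeModelSpec.main_effects_only())

    def test_collinear_design_names_columns(self, toy):
        dup = toy.covariates.assign(C2=toy.covariates["C"])
        data = ObservedData(
            treatment=toy.treatment,
            outcome=toy.outcome,
            covariates=dup,
            unit_id=toy.unit_id,
        )
        with pytest.raises(FitError, match="collinear") as exc:
            fit_outcome_model(data, OutcomeModelSpec.main_effects_only())
        assert exc.value.columns


class TestCounterfactualStack:
    def test_stack_shape_is_two_k_n(self, toy):
        stack = build_counterfactual_stack(toy, "ATT", K=1, seed=0)
        assert stack.n_pooled == 14
        assert stack.n_rows == 28

    def test_k200_gives_5600_rows(self, toy):
        stack = build_counterfactual_stack(toy, "ATT", K=200, seed=0)
        assert stack.n_rows == 5600

    def test_same_seed_identical_stacks(self, toy):
        a = build_counterfactual_stack(toy, "ATE", K=5, seed=42)
        b = build_counterfactual_stack(toy, "ATE", K=5, seed=42)
        np.testing.assert_array_equal(a.source_index, b.source_index)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_each_pooled_row_defined_once_per_arm(self, toy):
        stack = build_counterfactual_stack(toy, "ATT", K=3, seed=1)
        assert len(stack.po_index) == len(stack.po_reference) == stack.n_pooled
        assert np.isnan(stack.po_index).all()  # undefined before assignment

    def test_long_format_view(self, toy):
        stack = build_counterfactual_stack(toy, "ATT", K=2, seed=0)
        frame = stack.to_frame()
        assert len(frame) == stack.n_rows
        assert set(frame["intervention"]) == {0, 1}


class TestAssignPotentialOutcomes:
    def test_att_consistency_is_exact(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        stack = build_counterfactual_stack(toy, "ATT", K=50, seed=0)
        stack = assign_potential_outcomes(stack, model, seed=0)
        treated = stack.observed_treatment == 1
        np.testing.assert_array_equal(stack.po_index[treated], stack.observed_outcome[treated])

    def test_att_untreated_rows_stay_undefined(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        stack = build_counterfactual_stack(toy, "ATT", K=10, seed=0)
        stack = assign_potential_outcomes(stack, model, seed=0)
        untreated = stack.observed_treatment == 0
        assert np.isnan(stack.po_index[untreated]).all()
        assert np.isnan(stack.po_reference[untreated]).all()

    def test_atu_mirror_consistency(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        stack = build_counterfactual_stack(toy, "ATU", K=50, seed=3)
        stack = assign_potential_outcomes(stack, model, seed=3)
        untreated = stack.observed_treatment == 0
        np.testing.assert_array_equal(
            stack.po_reference[untreated], stack.observed_outcome[untreated]
        )
        assert np.isnan(stack.po_index[stack.observed_treatment == 1]).all()

    def test_defined_outcomes_are_binary(self, toy, toy_spec):
        model = fit_outcome_model(toy, toy_spec)
        for estimand in ("ATT", "ATU", "ATE"):
            stack = build_counterfactual_stack(toy, estimand, K=20, seed=5)
            stack = assign_potential_outcomes(stack, model, seed=5)
            for arm in (stack.po_index, stack.po_reference):
                defined = arm[~np.isnan(arm)]
                assert np.isin(defined, (0.0, 1.0)).all()

    def test_null_model_counterfactual_mean_near_half(self, null8):
        # all coefficients zero -> inverse-logit(0) = 0.5 in the simulated arm
        model = fit_outcome_model(null8, OutcomeModelSpec.saturated(null8.covariate_names))
        stack = build_counterfactual_stack(null8, "ATT", K=2000, seed=0)
        stack = assign_potential_outcomes(stack, model, seed=0)
        sim = stack.po_reference[~np.isnan(stack.po_reference)]
        assert abs(sim.mean() - 0.5) < 3 * np.sqrt(0.25 / sim.size)


class TestMarginalContrast:
    @staticmethod
    def _stack_with_means(n1, k1, n0, k0):
        """Stack whose index arm has k1/n1 successes and reference arm k0/n0."""
        from gcomp.estimators import CounterfactualStack

        m = max(n1, n0)
        po1 = np.full(m, np.nan)
        po0 = np.full(m, np.nan)
        po1[:n1] = np.r_[np.ones(k1), np.zeros(n1 - k1)]
        po0[:n0] = np.r_[np.ones(k0), np.zeros(n0 - k0)]
        return CounterfactualStack(
            estimand="ATT",
            k=1,
            n_source=m,
            source_index=np.arange(m),
            unit_id=np.arange(m),
            replicate=np.ones(m, dtype=int),
            covariates=pd.DataFrame({"C": np.zeros(m)}),
            observed_treatment=np.ones(m, dtype=np.int8),
            observed_outcome=np.ones(m, dtype=np.int8),
            po_index=po1,
            po_reference=po0,
        )

    def test_hand_arithmetic(self):
        stack = self._stack_with_means(12, 8, 12, 3)  # means 2/3 and 1/4
        assert marginal_contrast(stack, "RD") == pytest.approx(5 / 12, abs=1e-12)
        assert marginal_contrast(stack, "OR") == pytest.approx(6.0, abs=1e-12)

    def test_equal_means_null_contrast(self):
        stack = self._stack_with_means(10, 5, 10, 5)
        assert marginal_contrast(stack, "RD") == 0.0
        assert marginal_contrast(stack, "OR") == 1.0

    def test_degenerate_odds(self):
        stack = self._stack_with_means(10, 10, 10, 5)
        with pytest.raises(DegenerateOddsError):
            marginal_contrast(stack, "OR")

    def test_empty_arm_errors(self):
        stack = self._stack_with_means(10, 5, 10, 5)
        from dataclasses import replace

        empty = replace(stack, po_reference=np.full(10, np.nan))
        with pytest.raises(EstimationError):
            marginal_contrast(empty, "RD")


class TestStandardization:
    @pytest.mark.parametrize(
        "estimand,rd,orr",
        [("ATT", ATT_RD, ATT_OR), ("ATU", ATU_RD, ATU_OR), ("ATE", ATE_RD, ATE_OR)],
    )
    def test_toy_fixture_values(self, toy, toy_spec, estimand, rd, orr):
        assert standardization_estimate(toy, toy_spec, estimand, "RD") == pytest.approx(
            rd, abs=1e-8
        )
        assert standardization_estimate(toy, toy_spec, estimand, "OR") == pytest.approx(
            orr, abs=1e-8
        )

    def test_null_dataset_gives_zero(self, null8):
        spec = OutcomeModelSpec.saturated(null8.covariate_names)
        for estimand in ("ATT", "ATU", "ATE"):
            assert standardization_estimate(null8, spec, estimand, "RD") == pytest.approx(
                0.0, abs=1e-8
            )

    def test_weighted_average_identity(self, toy, toy_spec):
        att = standardization_estimate(toy, toy_spec, "ATT")
        atu = standardization_estimate(toy, toy_spec, "ATU")
        ate = standardization_estimate(toy, toy_spec, "ATE")
        p = toy.treated_fraction
        assert ate == pytest.approx(p * att + (1 - p) * atu, abs=1e-8)


class TestRestriction:
    def test_att_matches_standardization_under_interacted_model(self, toy, toy_spec):
        assert restriction_estimate(toy, toy_spec, "ATT") == pytest.approx(ATT_RD, abs=1e-8)
        assert restriction_estimate(toy, toy_spec, "ATU") == pytest.approx(ATU_RD, abs=1e-8)

    def test_ate_not_allowed(self, toy, toy_spec):
        with pytest.raises(ConfigurationError):
            restriction_estimate(toy, toy_spec, "ATE")

    def test_null_dataset_gives_zero(self, null8):
        spec = OutcomeModelSpec.saturated(null8.covariate_names)
        assert restriction_estimate(null8, spec, "ATT") == pytest.approx(0.0, abs=1e-8)


class TestNonparametricStandardization:
    @pytest.mark.parametrize(
        "estimand,rd,orr",
        [("ATT", ATT_RD, ATT_OR), ("ATU", ATU_RD, ATU_OR), ("ATE", ATE_RD, ATE_OR)],
    )
    def test_toy_fixture_values(self, toy, estimand, rd, orr):
        assert nonparametric_standardization(toy, estimand, "RD") == pytest.approx(
            rd, abs=1e-12
        )
        assert nonparametric_standardization(toy, estimand, "OR") == pytest.approx(
            orr, abs=1e-12
        )

    def test_single_stratum_collapses_to_crude_contrast(self):
        rng = np.random.default_rng(4)
        n = 50
        data = ObservedData(
            treatment=rng.integers(0, 2, n),
            outcome=rng.integers(0, 2, n),
            covariates=pd.DataFrame({"C": np.zeros(n, dtype=int)}),
            unit_id=np.arange(n),
        )
        crude = data.outcome[data.treatment == 1].mean() - data.outcome[
            data.treatment == 0
        ].mean()
        assert nonparametric_standardization(data, "ATE", "RD") == pytest.approx(crude)

    def test_positivity_violation_names_stratum(self):
        # stratum C=2 exists only among the treated: ATT needs E(Y | A=0, C=2)
        a = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        c = np.array([0, 0, 1, 0, 1, 1, 2, 2])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        data = ObservedData(
            treatment=a, outcome=y, covariates=pd.DataFrame({"C": c}), unit_id=np.arange(8)
        )
        with pytest.raises(PositivityError) as exc:
            nonparametric_standardization(data, "ATT", "RD")
        assert exc.value.stratum == (2,)

    def test_oracle_equivalence_two_discrete_covariates(self):
        """Saturated parametric standardization equals the model-free oracle."""
        rng = np.random.default_rng(7)
        n = 400
        c1 = rng.integers(0, 2, n)
        c2 = rng.choice(["x", "y", "z"], n)
        a = rng.binomial(1, 0.3 + 0.3 * c1)
        base = 0.2 + 0.2 * c1 + 0.1 * (c2 == "y") + 0.25 * a
        y = rng.binomial(1, np.clip(base, 0.05, 0.95))
        data = ObservedData(
            treatment=a,
            outcome=y,
            covariates=pd.DataFrame({"c1": c1, "c2": c2}),
            unit_id=np.arange(n),
        )
        spec = OutcomeModelSpec.saturated(data.covariate_names)
        for estimand in ("ATT", "ATU", "ATE"):
            for scale in ("RD", "OR"):
                oracle = nonparametric_standardization(data, estimand, scale)
                fitted = standardization_estimate(data, spec, estimand, scale)
                assert fitted == pytest.approx(oracle, abs=1e-8), (estimand, scale)


class TestScaleCoherence:
    @given(
        p1=st.floats(0.01, 0.99),
        p0=st.floats(0.01, 0.99),
    )
    def test_rd_sign_iff_or_side(self, p1, p0):
        rd = _contrast(p1, p0, "RD")
        orr = _contrast(p1, p0, "OR")
        assert (rd > 0) == (orr > 1) == (p1 > p0)

    def test_estimates_from_same_arm_means_are_coherent(self, toy, toy_spec):
        for estimand in ("ATT", "ATU", "ATE"):
            rd = standardization_estimate(toy, toy_spec, estimand, "RD")
            orr = standardization_estimate(toy, toy_spec, estimand, "OR")
            assert (rd > 0) == (orr > 1)
            assert -1.0 <= rd <= 1.0


class TestGcompute:
    def test_standardization_point_only(self, toy, toy_spec):
        req = EstimandRequest("ATT", "RD", method="standardization", J=0, seed=0)
        est = gcompute(toy, req, toy_spec)
        assert est.point == pytest.approx(ATT_RD, abs=1e-8)
        assert est.se is None and est.ci_low is None

    def test_simulation_converges_to_standardization(self, toy, toy_spec):
        req = EstimandRequest("ATT", "RD", method="simulation", K=2000, J=0, seed=11)
        est = gcompute(toy, req, toy_spec)
        assert est.point == pytest.approx(ATT_RD, abs=0.02)

    def test_determinism(self, toy, toy_spec):
        req = EstimandRequest("ATU", "RD", method="simulation", K=100, J=0, seed=9)
        a = gcompute(toy, req, toy_spec)
        b = gcompute(toy, req, toy_spec)
        assert a.point == b.point
        assert a.metadata == b.metadata

    def test_restriction_request_for_ate_rejected(self):
        with pytest.raises(ConfigurationError):
            EstimandRequest("ATE", "RD", method="restriction")

    def test_positivity_report_attached(self, toy, toy_spec):
        req = EstimandRequest("ATT", "RD", J=0, seed=0)
        est = gcompute(toy, req, toy_spec)
        assert est.metadata["positivity_n_flagged"] == 0


class TestHomogeneousGenerator:
    def test_estimands_agree_without_confounding_or_interaction(self):
        """No confounding, no effect modification: ATT = ATU = ATE up to noise."""
        config = SyntheticConfig(
            n=4000,
            alpha=(0.0, 0.0, 0.0),
            beta=(-1.0, 0.5, 0.4, 0.3, 0.0, 0.0),
            seed=2,
        )
        data = generate_dataset(config)
        spec = OutcomeModelSpec.default(data.covariate_names)
        est = {
            e: standardization_estimate(data, spec, e, "RD") for e in ("ATT", "ATU", "ATE")
        }
        # subgroup covariate distributions differ only by sampling noise
        assert abs(est["ATT"] - est["ATU"]) < 0.03
        assert min(est["ATT"], est["ATU"]) <= est["ATE"] <= max(est["ATT"], est["ATU"])
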