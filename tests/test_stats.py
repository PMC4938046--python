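"""Tests for the bee-choice statistics: counts, tests, intervals, mixed model."""

import subprocess
import textwrap
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from beelearn.stats import (
    CHANCE_LEVEL,
    ChoiceRecord,
    adjusted_wald_interval,
    chance_level,
    cued_reward_likelihood_ratio,
    exact_binomial_test,
    first_k_summary,
    fit_choice_glmm,
    group_proportion,
)
from beelearn.synth import GeneratorConfig, generate_choice_dataset


def _design(records, formula):
    from beelearn.stats import _design_matrix

    y, X, names, groups, n_groups = _design_matrix(records, formula)
    return y, X, names, groups, n_groups


class TestDesignConstants:
    def test_chance_level_is_one_third(self):
        assert chance_level() == pytest.approx(1 / 3)
        assert CHANCE_LEVEL == pytest.approx(4 / 12)

    def test_cued_flowers_three_times_more_likely_to_reward(self):
        assert cued_reward_likelihood_ratio() == pytest.approx(3.0)


class TestChoiceRecord:
    def test_first_choice_is_first_landing(self):
        record = ChoiceRecord("b1", "c1", 1, 0, (0, 1, 1))
        assert record.first_choice_cued == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cue_type": 2},
            {"distribution": -1},
            {"landings": ()},
            {"landings": (0, 2)},
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        base = {"bee_id": "b1", "colony": "c1", "cue_type": 1, "distribution": 0, "landings": (1,)}
        with pytest.raises(ValueError):
            ChoiceRecord(**{**base, **kwargs})


class TestGroupProportion:
    def test_counts_first_choices(self):
        records = [
            ChoiceRecord(f"b{i}", "c1", 1, 0, (1 if i < 12 else 0,)) for i in range(16)
        ]
        assert group_proportion(records, 1, 0) == (12, 16, 0.75)

    def test_all_misses(self):
        records = [ChoiceRecord(f"b{i}", "c1", 0, 1, (0,)) for i in range(5)]
        assert group_proportion(records, 0, 1) == (0, 5, 0.0)

    def test_empty_group_raises(self):
        records = [ChoiceRecord("b1", "c1", 1, 0, (1,))]
        with pytest.raises(ValueError, match="no records"):
            group_proportion(records, 0, 0)

    def test_default_design_group_sizes(self, default_records):
        assert group_proportion(default_records, 1, 0)[1] == 16
        assert group_proportion(default_records, 1, 1)[1] == 17
        assert group_proportion(default_records, 0, 0)[1] == 12
        assert group_proportion(default_records, 0, 1)[1] == 12


class TestExactBinomial:
    def test_certain_success_closed_form(self):
        result = exact_binomial_test(16, 16, p0=1 / 3, alternative="greater")
        assert result.p_value == pytest.approx((1 / 3) ** 16, rel=1e-12)

    def test_null_consistent_count_keeps_high_p(self):
        assert exact_binomial_test(4, 12).p_value >= 0.99

    @pytest.mark.parametrize("k,n", [(12, 16), (0, 10), (7, 7), (5, 21)])
    def test_matches_exhaustive_enumeration(self, k, n):
        expected = oracles.enumerate_binomial_two_sided(k, n, Fraction(1, 3))
        assert exact_binomial_test(k, n).p_value == pytest.approx(expected, rel=1e-9)

    def test_one_sided_p_non_increasing_in_k(self):
        p_values = [
            exact_binomial_test(k, 20, alternative="greater").p_value for k in range(21)
        ]
        assert all(a >= b for a, b in zip(p_values, p_values[1:]))

    @pytest.mark.parametrize("k,n,p0", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0), (2, 5, 1.0)])
    def test_invalid_inputs_rejected(self, k, n, p0):
        with pytest.raises(ValueError):
            exact_binomial_test(k, n, p0)


class TestAdjustedWald:
    def test_symmetric_at_half(self):
        result = adjusted_wald_interval(8, 16)
        assert result.point == pytest.approx(0.5)
        assert result.upper - result.point == pytest.approx(result.point - result.lower)

    def test_lower_bound_clamped(self):
        result = adjusted_wald_interval(0, 10)
        assert result.lower == 0.0

    @pytest.mark.parametrize("k,n,confidence", [(12, 16, 0.90), (3, 57, 0.95), (1, 2, 0.5)])
    def test_matches_direct_formula(self, k, n, confidence):
        point, lower, upper = oracles.agresti_coull_direct(k, n, confidence)
        result = adjusted_wald_interval(k, n, confidence)
        assert result.point == pytest.approx(point, abs=1e-10)
        assert result.lower == pytest.approx(lower, abs=1e-10)
        assert result.upper == pytest.approx(upper, abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        lower, upper = proportion_confint(12, 16, alpha=0.10, method="agresti_coull")
        result = adjusted_wald_interval(12, 16, 0.90)
        assert result.lower == pytest.approx(lower, abs=1e-10)
        assert result.upper == pytest.approx(upper, abs=1e-10)

    def test_width_shrinks_with_sample_size(self):
        widths = [
            adjusted_wald_interval(3 * m, 4 * m).upper - adjusted_wald_interval(3 * m, 4 * m).lower
            for m in (1, 4, 16, 64)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @given(k=st.integers(0, 200), extra=st.integers(0, 200))
    @settings(deadline=None, max_examples=60)
    def test_interval_stays_in_unit_range(self, k, extra):
        result = adjusted_wald_interval(k, k + extra + 1)
        assert 0.0 <= result.lower <= result.point <= result.upper <= 1.0


class TestFirstKSummary:
    def test_per_bee_proportion(self):
        records = [ChoiceRecord("b1", "c1", 1, 0, (1, 0, 1, 0))]
        out = first_k_summary(records, 4)
        assert out["mean_proportion"].iloc[0] == pytest.approx(0.5)

    def test_short_sequences_use_available_landings(self):
        records = [ChoiceRecord("b1", "c1", 1, 0, (1, 1))]
        out = first_k_summary(records, 10)
        assert out["mean_proportion"].iloc[0] == pytest.approx(1.0)

    def test_k1_reduces_to_group_proportion(self, default_records):
        out = first_k_summary(default_records, 1)
        for _, row in out.iterrows():
            _, _, prop = group_proportion(
                default_records, int(row["cue_type"]), int(row["distribution"])
            )
            assert row["mean_proportion"] == pytest.approx(prop)

    def test_invalid_k_rejected(self, default_records):
        with pytest.raises(ValueError):
            first_k_summary(default_records, 0)

    @pytest.mark.parametrize("k", [1, 4, 10])
    def test_social_high_variance_group_stays_highest(self, default_records, k):
        out = first_k_summary(default_records, k).set_index(["cue_type", "distribution"])
        top = out["mean_proportion"].idxmax()
        assert top == (1, 0)  # social cue, high-variance prior experience


class TestGlmm:
    def test_null_design_recovers_zero_effects(self):
        config = GeneratorConfig(
            group_sizes={(1, 0): 1000, (1, 1): 1000, (0, 0): 1000, (0, 1): 1000},
            colony_sd=0.0,
            full_effects={"cue_type": 0.0, "distribution": 0.0, "interaction": 0.0},
            n_landings_per_bee=1,
            seed=77,
        )
        fit = fit_choice_glmm(generate_choice_dataset(config), "full_interaction")
        for term in ("cue_type", "distribution", "cue_type:distribution"):
            assert abs(fit.coefficients[term]) < 3 * fit.standard_errors[term]

    def test_single_colony_reduces_to_plain_logit(self, forty_bee_records):
        import statsmodels.api as sm

        records = [
            ChoiceRecord(r.bee_id, "only_colony", r.cue_type, r.distribution, r.landings)
            for r in forty_bee_records
        ]
        with pytest.warns(UserWarning, match="one colony"):
            fit = fit_choice_glmm(records, "full_interaction")
        y, X, names, _, _ = _design(records, "full_interaction")
        reference = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.random_intercept_sd == 0.0
        np.testing.assert_allclose(
            [fit.coefficients[t] for t in names], reference.params, atol=1e-4
        )

    def test_matches_gauss_hermite_direct_optimisation(self, forty_bee_records):
        fit = fit_choice_glmm(forty_bee_records, "full_interaction")
        y, X, names, groups, _ = _design(forty_bee_records, "full_interaction")
        params, oracle_ll = oracles.fit_glmm_by_nelder_mead(y, X, groups)
        assert fit.loglik == pytest.approx(oracle_ll, abs=1e-3)
        np.testing.assert_allclose(
            [fit.coefficients[t] for t in names], params[:-1], atol=1e-2
        )

    def test_matches_lme4_glmer(self, forty_bee_records, tmp_path):
        import json
        import pandas as pd

        frame = pd.DataFrame(
            {
                "y": [r.first_choice_cued for r in forty_bee_records],
                "cue": [r.cue_type for r in forty_bee_records],
                "dist": [r.distribution for r in forty_bee_records],
                "colony": [r.colony for r in forty_bee_records],
            }
        )
        csv = tmp_path / "d.csv"
        frame.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ cue * dist + (1 | colony), data = d, family = binomial, nAGQ = 25)
            out <- list(coef = as.numeric(fixef(m)),
                        sigma = as.numeric(sqrt(unlist(VarCorr(m)))),
                        loglik = as.numeric(logLik(m)))
            cat(jsonlite::toJSON(out, digits = 12))
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        reference = json.loads(proc.stdout)
        fit = fit_choice_glmm(forty_bee_records, "full_interaction")
        names = ["intercept", "cue_type", "distribution", "cue_type:distribution"]
        np.testing.assert_allclose(
            [fit.coefficients[t] for t in names], reference["coef"], atol=1e-3
        )
        assert fit.random_intercept_sd == pytest.approx(reference["sigma"][0], abs=1e-3)
        assert fit.loglik == pytest.approx(reference["loglik"][0], abs=1e-4)

    def test_wald_z_consistency(self, forty_bee_records):
        fit = fit_choice_glmm(forty_bee_records, "full_interaction")
        for term, coef in fit.coefficients.items():
            assert fit.z_values[term] == pytest.approx(
                coef / fit.standard_errors[term], abs=1e-6
            )
            assert 0.0 <= fit.p_values[term] <= 1.0

    def test_complete_separation_is_flagged(self):
        records = []
        for i in range(30):
            cue = i % 2
            records.append(
                ChoiceRecord(f"b{i}", f"c{i % 3 + 1}", cue, i // 15, (cue,))
            )
        fit = fit_choice_glmm(records, "full_interaction")
        assert fit.separation

    def test_distribution_only_formula_on_social_subset(self, default_records):
        social = [r for r in default_records if r.cue_type == 1]
        fit = fit_choice_glmm(social, "distribution_only")
        assert set(fit.coefficients) == {"intercept", "distribution"}
        # no-variance bees land on cues less often in the default design
        assert fit.coefficients["distribution"] < 0

    def test_unknown_formula_rejected(self, default_records):
        with pytest.raises(ValueError):
            fit_choice_glmm(default_records, "cue_only")
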