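"""Differential expression: normalization, moderation, thresholds, overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirpair.diffexpr import (
    ModeratedFit,
    de_table,
    fit_two_group,
    moderate_variances,
    quantile_normalize,
    venn_overlap,
)
from mirpair.io import ExpressionMatrix
from mirpair.synthetic import SimulationConfig, simulate_expression


def matrix_of(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(tuple(features), tuple(samples), values)


def sheet_of(samples, groups, platform="miRNA"):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": [f"subj{i}" for i in range(len(samples))],
            "group": groups,
            "platform": platform,
        }
    )


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        m = matrix_of([[1, 1], [5, 5], [3, 3]])
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_two_by_two_example(self):
        m = matrix_of([[1, 3], [2, 4]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2, 2], [3, 3]])

    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(0)
        out = quantile_normalize(matrix_of(rng.normal(size=(50, 6))))
        cols = np.sort(out.values, axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(cols[:, j], cols[:, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = quantile_normalize(matrix_of(rng.normal(size=(30, 4))))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_single_sample_warns_identity(self):
        m = matrix_of([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)


class TestTwoGroupFit:
    def test_identical_groups_zero_fold_change(self):
        m = matrix_of([[1, 1, 1, 1], [7, 7, 7, 7]])
        fit = fit_two_group(m, sheet_of(list(m.sample_ids), ["active_UC"] * 2 + ["control"] * 2), "active_UC", "control")
        np.testing.assert_allclose(fit.log2fc, [0, 0])

    def test_hand_computed_fold_change_and_variance(self):
        m = matrix_of([[2, 2, 1, 1], [3, 1, 0, 0]])
        fit = fit_two_group(m, sheet_of(list(m.sample_ids), ["active_UC"] * 2 + ["control"] * 2), "active_UC", "control")
        np.testing.assert_allclose(fit.log2fc, [1.0, 2.0])
        np.testing.assert_allclose(fit.s_sq, [0.0, 1.0])  # pooled (2+0)/2
        assert fit.df_residual == 2

    def test_small_group_rejected(self):
        m = matrix_of([[1, 2, 3]])
        sheet = sheet_of(list(m.sample_ids), ["active_UC", "control", "control"])
        with pytest.raises(ValueError):
            fit_two_group(m, sheet, "active_UC", "control")


class TestModeration:
    def test_d0_zero_keeps_sample_variances(self):
        s_sq = np.array([0.5, 1.0, 2.0])
        fit = moderate_variances(s_sq, df=4, d0=0.0)
        np.testing.assert_allclose(fit.s_tilde_sq, s_sq)

    def test_d0_infinite_pools_completely(self):
        s_sq = np.array([0.5, 1.0, 2.0])
        fit = moderate_variances(s_sq, df=4, d0=math.inf, s0_sq=1.2)
        np.testing.assert_allclose(fit.s_tilde_sq, 1.2)

    def test_shrinkage_formula(self):
        fit = moderate_variances(np.array([1.0]), df=2, d0=2.0, s0_sq=2.0)
        assert fit.s_tilde_sq[0] == pytest.approx(1.5)  # (2*2 + 2*1) / (2+2)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(2)
        s_sq = 0.5 * rng.chisquare(6, size=500) / 6
        fit = moderate_variances(s_sq, df=6)
        lo = np.minimum(s_sq, fit.s0_sq)
        hi = np.maximum(s_sq, fit.s0_sq)
        assert np.all(fit.s_tilde_sq >= lo - 1e-12) and np.all(fit.s_tilde_sq <= hi + 1e-12)

    def test_equal_variances_hit_infinite_prior_df(self):
        # degenerate scatter: complete pooling, one common posterior variance
        fit = moderate_variances(np.full(50, 0.7), df=5)
        assert math.isinf(fit.d0)
        np.testing.assert_allclose(fit.s_tilde_sq, fit.s0_sq)
        # the log-scale bias correction keeps s0^2 on the variance scale
        assert 0.5 < fit.s0_sq < 1.0

    def test_hyperparameter_recovery_from_scaled_f(self):
        # variances drawn from the conjugate model: s^2 ~ s0^2 * F(df, d0)
        rng = np.random.default_rng(3)
        d0_true, s0_true, df = 8.0, 0.9, 6
        chi_prior = rng.chisquare(d0_true, size=20000)
        chi_resid = rng.chisquare(df, size=20000)
        s_sq = s0_true * d0_true / chi_prior * chi_resid / df
        fit = moderate_variances(s_sq, df=df)
        assert fit.d0 == pytest.approx(d0_true, rel=0.15)
        assert fit.s0_sq == pytest.approx(s0_true, rel=0.1)


class TestDeTable:
    def build(self, rng, n_features=200, shift=0.0, n_shifted=0, n_per_group=5, sd=0.5):
        values = rng.normal(8.0, sd, size=(n_features, 2 * n_per_group))
        values[:n_shifted, :n_per_group] += shift
        m = matrix_of(values)
        sheet = sheet_of(list(m.sample_ids), ["active_UC"] * n_per_group + ["control"] * n_per_group)
        fit = fit_two_group(m, sheet, "active_UC", "control")
        return fit

    def test_no_signal_yields_no_calls(self):
        fit = self.build(np.random.default_rng(4))
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual))
        assert table["significant"].sum() == 0

    def test_threshold_rule_requires_both_gates(self):
        # construct a fit manually so FC and fdr can be pinned
        from mirpair.diffexpr import TwoGroupFit

        fit = TwoGroupFit(
            feature_ids=("big_fc", "small_fc", "weak_p"),
            log2fc=np.array([1.1, 0.9, 2.0]),
            s_sq=np.array([0.01, 0.01, 10.0]),
            df_residual=8,
            avg_expr=np.zeros(3),
            n_a=5,
            n_b=5,
        )
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual, d0=0.0)).set_index("feature_id")
        assert bool(table.loc["big_fc", "significant"])
        assert not bool(table.loc["small_fc", "significant"])  # FC gate fails
        assert not bool(table.loc["weak_p", "significant"])  # FDR gate fails
        assert table.loc["weak_p", "fdr"] > 0.05

    def test_signed_linear_fold_change_convention(self):
        fit = self.build(np.random.default_rng(5), n_features=20, shift=-1.5749, n_shifted=1, sd=0.01)
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual))
        # log2FC about -1.575 should print as FC about -2.98
        assert table.loc[0, "FC"] == pytest.approx(-2.98, abs=0.1)

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(50, 12))
        m = matrix_of(values)
        sheet = sheet_of(list(m.sample_ids), ["active_UC"] * 6 + ["control"] * 6)
        fit = fit_two_group(m, sheet, "active_UC", "control")
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual, d0=0.0))
        ref = sps.ttest_ind(values[:, :6], values[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose(table["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(table["p"], ref.pvalue, atol=1e-10)

    def test_infinite_d0_orders_t_by_fold_change(self):
        fit = self.build(np.random.default_rng(7), n_features=100)
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual, d0=math.inf, s0_sq=0.25))
        order_t = np.argsort(-np.abs(table["t"].to_numpy()))
        order_fc = np.argsort(-np.abs(table["log2FC"].to_numpy()))
        np.testing.assert_array_equal(order_t, order_fc)

    def test_recovers_planted_two_fold_changes(self):
        # planted |log2FC| = 2 at 10 vs 10, noise sd 0.5: >= 90% sensitivity
        rng = np.random.default_rng(8)
        n_planted = 40
        values = rng.normal(8.0, 0.5, size=(400, 20))
        signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
        values[:n_planted, :10] += 2.0 * signs[:, None]
        m = matrix_of(values)
        sheet = sheet_of(list(m.sample_ids), ["active_UC"] * 10 + ["control"] * 10)
        fit = fit_two_group(m, sheet, "active_UC", "control")
        table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual))
        recovered = table["significant"].to_numpy()[:n_planted].mean()
        assert recovered >= 0.9
        assert table["significant"].to_numpy()[n_planted:].mean() <= 0.01

    def test_null_false_positive_fraction_across_seeds(self):
        # global null: fraction of features called at FDR < 0.05 stays <= 0.05
        fractions = []
        for seed in range(20):
            fit = self.build(np.random.default_rng(100 + seed), n_features=300)
            table = de_table(fit, moderate_variances(fit.s_sq, fit.df_residual))
            fractions.append((table["fdr"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05


class TestVennOverlap:
    @staticmethod
    def de_frame(rows):
        return pd.DataFrame(
            [
                {"feature_id": f, "log2FC": fc, "significant": sig}
                for f, fc, sig in rows
            ]
        )

    def test_direction_matched_overlap(self):
        a = self.de_frame([("m1", 2.0, True), ("m2", -2.0, True), ("m3", 1.5, True)])
        b = self.de_frame([("m2", -1.2, True), ("m3", -1.2, True)])
        assert venn_overlap(a, b) == {"total": 1, "up": 0, "down": 1}

    def test_disjoint_sets(self):
        a = self.de_frame([("m1", 2.0, True)])
        b = self.de_frame([("m2", 2.0, True)])
        assert venn_overlap(a, b)["total"] == 0

    def test_identical_sets_fully_overlap(self):
        a = self.de_frame([("m1", 2.0, True), ("m2", -2.0, True)])
        assert venn_overlap(a, a) == {"total": 2, "up": 1, "down": 1}


def test_planted_fold_change_within_sampling_error():
    config = SimulationConfig(seed=11)
    mirna_expr, _, sheet, truth = simulate_expression(config)
    frame = mirna_expr.to_frame()
    active = sheet.query("platform == 'miRNA' and group == 'active_UC'")["sample_id"]
    control = sheet.query("platform == 'miRNA' and group == 'control'")["sample_id"]
    bound = 3 * config.noise_sd * math.sqrt(1 / len(active) + 1 / len(control))
    for feature, direction in truth.de_mirna.items():
        observed = frame.loc[feature, active].mean() - frame.loc[feature, control].mean()
        assert abs(observed - direction * config.de_log2fc) < bound
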