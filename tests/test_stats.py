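"""Group inference and behavioral correlation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fconn.errors import ComputationError, ValidationError
from fconn.experiments import exhaustive_permutation_p
from fconn.network import SparsityGrid
from fconn.stats import (
    behavior_correlation_screen,
    global_metric_comparison,
    partial_correlation,
    per_node_threshold,
    permutation_test_nodal,
    pooled_t_test,
    t_test_from_summary,
)


class TestPooledTTest:
    def test_hand_computed_small_samples(self):
        res = pooled_t_test(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = pooled_t_test(a, a.copy())
        assert res.t == 0.0

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.raises(ComputationError):
            pooled_t_test(np.array([1.0, 1.0]), np.array([2.0, 2.0]))

    @given(
        st.floats(-3, 3), st.floats(0.1, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_antisymmetry_and_affine_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=10)
        b = rng.normal(size=12)
        res = pooled_t_test(a, b)
        assert pooled_t_test(b, a).t == pytest.approx(-res.t)
        res2 = pooled_t_test(scale * a + shift, scale * b + shift)
        assert res2.t == pytest.approx(res.t, rel=1e-9)

    def test_matches_summary_route(self, rng):
        a = rng.normal(size=18)
        b = rng.normal(size=18)
        raw = pooled_t_test(a, b)
        summ = t_test_from_summary(
            a.mean(), a.std(ddof=1), 18, b.mean(), b.std(ddof=1), 18
        )
        assert summ.t == pytest.approx(raw.t)
        assert summ.p == pytest.approx(raw.p)


class TestSummaryTTest:
    """Published group summaries of an impulsivity questionnaire (two
    groups of 18) must reproduce their printed t statistics."""

    def test_total_score_row(self):
        res = t_test_from_summary(76.06, 8.26, 18, 64.89, 11.14, 18)
        assert res.t == pytest.approx(3.417, abs=5e-4)
        assert res.df == 34
        assert res.p < 0.01

    def test_motor_subscale_row(self):
        res = t_test_from_summary(26.89, 4.76, 18, 20.61, 4.16, 18)
        assert res.t == pytest.approx(4.211, abs=0.01)

    def test_nonplanning_subscale_row(self):
        res = t_test_from_summary(30.78, 4.43, 18, 26.44, 5.24, 18)
        assert res.t == pytest.approx(2.681, abs=0.01)

    def test_equal_means_give_zero(self):
        assert t_test_from_summary(5, 1, 10, 5, 1, 10).t == 0.0


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r, _ = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_identity_gives_unit_correlation(self, rng):
        x = rng.normal(size=20)
        cov = rng.normal(size=(20, 2))
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_shared_confounder_removed(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=10_000)
        x = z + rng.normal(size=10_000)
        y = z + rng.normal(size=10_000)
        r_plain, _ = partial_correlation(x, y)
        r_partial, _ = partial_correlation(x, y, z[:, None])
        assert r_plain > 0.3
        assert abs(r_partial) < 0.1

    def test_zero_variance_is_reported_not_nan(self):
        with pytest.raises(ComputationError, match="undefined"):
            partial_correlation(np.ones(10), np.arange(10.0))

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValidationError, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestPerNodeThreshold:
    def test_ninety_nodes(self):
        assert per_node_threshold(90) == pytest.approx(1 / 90)
        assert round(per_node_threshold(90), 3) == 0.011

    def test_trivial_counts(self):
        assert per_node_threshold(1) == 1.0
        assert per_node_threshold(200) == 0.005


class TestPermutationTest:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(4, 1))
        b = rng.normal(loc=1.0, size=(4, 1))
        exact = exhaustive_permutation_p(a, b)
        n_perm = 5000
        table = permutation_test_nodal(a, b, n_perm=n_perm, seed=0)
        assert table["p"].iloc[0] == pytest.approx(exact, abs=2 / np.sqrt(n_perm))

    def test_p_values_bounded_away_from_zero_and_one(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(loc=10.0, size=(6, 3))
        table = permutation_test_nodal(a, b, n_perm=200, seed=1)
        assert (table["p"] > 0).all()
        assert (table["p"] <= 1).all()
        assert table["p"].min() == pytest.approx(1 / 201)

    def test_seeded_runs_bit_reproducible(self, rng):
        a = rng.normal(size=(8, 5))
        b = rng.normal(size=(8, 5))
        cov = rng.normal(size=(16, 2))
        t1 = permutation_test_nodal(a, b, cov, n_perm=300, seed=42)
        t2 = permutation_test_nodal(a, b, cov, n_perm=300, seed=42)
        assert t1.equals(t2)

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValidationError):
            permutation_test_nodal(
                rng.normal(size=(2, 3)), rng.normal(size=(8, 3))
            )

    def test_tiny_n_perm_warns(self, rng):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test_nodal(
                rng.normal(size=(4, 2)), rng.normal(size=(4, 2)), n_perm=50
            )

    def test_covariate_adjustment_removes_confounded_difference(self):
        # group difference entirely explained by the covariate
        rng = np.random.default_rng(9)
        cov = np.concatenate([rng.normal(0, 1, 12), rng.normal(3, 1, 12)])
        values = (2.0 * cov + rng.normal(0, 0.1, 24))[:, None]
        adjusted = permutation_test_nodal(
            values[:12], values[12:], cov[:, None], n_perm=500, seed=3
        )
        raw = permutation_test_nodal(
            values[:12], values[12:], None, n_perm=500, seed=3
        )
        assert raw["p"].iloc[0] < 0.01
        assert adjusted["p"].iloc[0] > 0.05


class TestGlobalMetricComparison:
    def test_identical_groups_give_zero_t(self, rng):
        grid = SparsityGrid.from_range(0.11, 0.15, 0.01)
        curves = {"Eglo": rng.normal(size=(5, len(grid)))}
        out = global_metric_comparison(curves, {"Eglo": curves["Eglo"].copy()}, grid)
        assert np.allclose(out["t"], 0.0)
        assert (out["df"] == 8).all()

    def test_rows_cover_grid_plus_auc(self, rng):
        grid = SparsityGrid.from_range(0.11, 0.20, 0.01)
        curves_a = {"Cp": rng.normal(size=(4, len(grid)))}
        curves_b = {"Cp": rng.normal(size=(6, len(grid)))}
        out = global_metric_comparison(curves_a, curves_b, grid)
        assert len(out) == len(grid) + 1
        assert (out["sparsity"] == "AUC").sum() == 1

    def test_grid_mismatch_rejected(self, rng):
        grid = SparsityGrid.from_range(0.11, 0.20, 0.01)
        with pytest.raises(ValidationError):
            global_metric_comparison(
                {"Cp": rng.normal(size=(4, 3))},
                {"Cp": rng.normal(size=(4, 3))},
                grid,
            )


class TestBehaviorScreen:
    def test_planted_association_flagged(self):
        rng = np.random.default_rng(2)
        n, nodes = 36, 10
        aucs = rng.normal(size=(n, nodes))
        scores = 2.0 * aucs[:, 4] + 0.5 * rng.normal(size=n)
        out = behavior_correlation_screen(
            {"degree": aucs}, pd.DataFrame({"total": scores})
        )
        hit = out[(out["node"] == 4)].iloc[0]
        assert hit["significant_per_node"]
        assert hit["r"] > 0.5
        others = out[out["node"] != 4]
        assert others["significant_per_node"].sum() <= 2

    def test_missing_scores_are_dropped(self):
        rng = np.random.default_rng(3)
        aucs = rng.normal(size=(12, 3))
        scores = rng.normal(size=12)
        scores[[2, 7]] = np.nan
        out = behavior_correlation_screen(
            {"degree": aucs}, pd.DataFrame({"total": scores})
        )
        assert len(out) == 3  # one row per node, computed on 10 subjects

    def test_constant_score_is_an_error(self, rng):
        with pytest.raises(ComputationError, match="constant"):
            behavior_correlation_screen(
                {"degree": rng.normal(size=(10, 2))},
                pd.DataFrame({"total": np.ones(10)}),
            )
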