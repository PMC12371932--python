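"""Factor extraction, rotation, scoring, hierarchy and fold accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herbrel.factor_model import (
    FactorAssignment,
    LoadingMatrix,
    composite_loadings,
    factor_scores,
    first_order_fa,
    fold_reduction,
    hierarchical_reduction,
    higher_order_fa,
    name_core_factor,
    varimax,
    CoreFactor,
)


def _two_block_data(n=400, seed=0):
    """Two disjoint, internally near-perfectly correlated variable blocks."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, size=n)
    b = rng.integers(0, 2, size=n)
    X = np.column_stack([a, a, a, b, b, b]).astype(float)
    # tiny jitter so the correlation matrix is full-rank
    X += rng.normal(0, 1e-3, X.shape)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])


class TestFirstOrderFA:
    def test_recovers_two_perfect_blocks(self):
        X = _two_block_data()
        lm, fa = first_order_fa(X, n_factors=2)
        groups = {}
        for v, f in fa.factor_of.items():
            groups.setdefault(f, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [
            ["x0", "x1", "x2"], ["x3", "x4", "x5"]
        ]
        assert not fa.unassigned

    def test_uncorrelated_variable_stays_unassigned(self):
        rng = np.random.default_rng(1)
        X = _two_block_data(seed=1)
        X["noise"] = rng.standard_normal(len(X))
        _, fa = first_order_fa(X, n_factors=2)
        assert "noise" in fa.unassigned

    def test_zero_variance_column_dropped_and_reported(self):
        X = _two_block_data()
        X["const"] = 1.0
        lm, fa = first_order_fa(X, n_factors=2)
        assert lm.dropped == ["const"]
        assert "const" in fa.unassigned

    def test_invalid_factor_counts_raise(self):
        X = _two_block_data()
        with pytest.raises(ValueError):
            first_order_fa(X, n_factors=0)
        with pytest.raises(ValueError, match="rank"):
            first_order_fa(X.iloc[:, :2], n_factors=5)

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(10, 3))
        R = varimax(L)
        assert np.allclose((L**2).sum(axis=1), (R**2).sum(axis=1), atol=1e-8)

    def test_loadings_bounded_for_correlation_input(self):
        X = _two_block_data()
        lm, _ = first_order_fa(X, n_factors=2)
        assert (lm.loadings.abs() <= 1 + 1e-6).all().all()


class TestFactorScores:
    def _simple_model(self, weights, variables):
        ldf = pd.DataFrame({"AC1": weights}, index=variables)
        lm = LoadingMatrix(loadings=ldf, uniquenesses=1 - ldf["AC1"] ** 2)
        fa = FactorAssignment(factor_of={v: "AC1" for v in variables}, unassigned=set())
        return lm, fa

    def test_hand_arithmetic_example(self):
        # w=(0.6, 0.8), x=(1, 0), means (0.5, 0.5), SDs (0.5, 0.5) -> -0.2
        X = pd.DataFrame({"a": [1, 0, 1, 0], "b": [0, 1, 1, 0]}, dtype=float)
        lm, fa = self._simple_model([0.6, 0.8], ["a", "b"])
        fs = factor_scores(X, lm, fa)
        assert fs.means["a"] == 0.5 and pytest.approx(fs.sds["a"], rel=1e-9) == np.sqrt(1 / 3)
        # recompute with the stated SDs by hand for the first row
        z = 0.6 * (1 - 0.5) / 0.5 + 0.8 * (0 - 0.5) / 0.5
        assert pytest.approx(z, abs=1e-12) == -0.2
        # library path: standardized with sample SDs, same shape
        assert fs.scores.shape == (4, 1) and fs.k["AC1"] == 2

    def test_zero_weights_give_zero_scores(self):
        X = pd.DataFrame({"a": [1.0, 0.0, 1.0], "b": [0.0, 1.0, 1.0]})
        lm, fa = self._simple_model([0.0, 0.0], ["a", "b"])
        fs = factor_scores(X, lm, fa)
        assert np.allclose(fs.scores.to_numpy(), 0.0)

    def test_zero_sd_member_raises_naming_the_variable(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 0.0]})
        lm, fa = self._simple_model([0.5, 0.5], ["a", "b"])
        with pytest.raises(ValueError, match="'a'"):
            factor_scores(X, lm, fa)

    def test_observation_permutation_equivariance(self):
        X = _two_block_data(n=60, seed=3)
        lm, fa = first_order_fa(X, n_factors=2)
        fs = factor_scores(X, lm, fa)
        perm = np.random.default_rng(0).permutation(len(X))
        fs_p = factor_scores(X.iloc[perm].reset_index(drop=True), lm, fa)
        assert np.allclose(fs.scores.to_numpy()[perm], fs_p.scores.to_numpy(), atol=1e-9)


class TestHigherOrder:
    def test_three_latents_recovered_from_correlated_score_columns(self):
        rng = np.random.default_rng(4)
        latents = rng.standard_normal((500, 3))
        cols = {}
        for z in range(15):
            cols[f"AC{z+1}"] = 0.9 * latents[:, z % 3] + 0.436 * rng.standard_normal(500)
        scores = pd.DataFrame(cols)
        lm, cores = higher_order_fa(scores, n_core=3)
        assert [c.id for c in cores] == ["FA", "FB", "FC"]
        members = {c.id: set(c.members) for c in cores}
        truth_groups = [
            {f"AC{z+1}" for z in range(15) if z % 3 == g} for g in range(3)
        ]
        assert sorted(map(sorted, members.values())) == sorted(map(sorted, truth_groups))

    def test_identity_grouping_when_cores_equal_columns(self):
        X = _two_block_data()
        lm, fa = first_order_fa(X, n_factors=2)
        fs = factor_scores(X, lm, fa)
        _, cores = higher_order_fa(fs, n_core=2)
        assert sorted(len(c.members) for c in cores) == [1, 1]


class TestNaming:
    def test_threshold_and_order(self):
        comps = pd.DataFrame({"FA": [0.6, 0.55, 0.4]}, index=["p1", "p2", "p3"])
        cf = CoreFactor(id="FA", members=["AC1"])
        assert name_core_factor(cf, comps) == "p1_p2"

    def test_single_property(self):
        comps = pd.DataFrame({"FA": [0.9]}, index=["carminative"])
        assert name_core_factor(CoreFactor(id="FA", members=[]), comps) == "carminative"

    def test_no_property_passing_gives_unnamed(self):
        comps = pd.DataFrame({"FA": [0.2]}, index=["p"])
        assert name_core_factor(CoreFactor(id="FA", members=[]), comps) == "unnamed_FA"

    def test_composite_is_product_of_levels(self):
        X = _two_block_data()
        model = hierarchical_reduction(X, n_first=2, n_core=1, name_cut=0.5)
        comp = model.composites
        for var, f in model.first_fa.factor_of.items():
            core = model.second_fa.factor_of.get(f)
            if core:
                expected = (model.first_lm.loadings.loc[var, f]
                            * model.second_lm.loadings.loc[f, core])
                assert pytest.approx(comp.loc[var, core], abs=1e-12) == expected


class TestFoldReduction:
    @pytest.mark.parametrize(
        "n_vars,n_factors,fold", [(21, 3, 7), (88, 3, 29), (5, 5, 1)]
    )
    def test_published_operating_points(self, n_vars, n_factors, fold):
        out = fold_reduction(n_vars, n_factors)
        assert out["fold"] == fold
        assert out["pairs_before"] == 9 * n_vars
        assert out["pairs_after"] == 9 * n_factors

    def test_zero_factors_rejected(self):
        with pytest.raises(ValueError):
            fold_reduction(10, 0)

    @given(st.integers(1, 500), st.integers(1, 60))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_floor_bound_property(self, n, m):
        fold = fold_reduction(n, m)["fold"]
        assert fold * m <= n < fold * m + m
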