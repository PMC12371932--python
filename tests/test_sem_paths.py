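"""Path regression: OLS estimates, significance filtering, sign narratives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from herbrel import examples_data as D
from herbrel.sem_paths import (
    PathEstimate,
    extract_relations,
    fit_paths,
    interpret_sign,
)


def _brute_force_ols(y, X):
    """Normal-equations solver with classical standard errors (oracle)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ y
    resid = y - Xd @ beta
    dof = len(y) - Xd.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se, dof


def _one_hot(parts, n_parts):
    P = np.zeros((len(parts), n_parts))
    P[np.arange(len(parts)), parts] = 1
    return P


class TestFitPaths:
    def test_textbook_two_group_slope(self):
        # y=(1,2,3,4) on x=(0,0,1,1): slope 2.0, SE ~ 0.7071, p(df=2) ~ 0.106
        y = np.array([1.0, 2.0, 3.0, 4.0])
        parts = np.array([0, 0, 1, 1])
        est = fit_paths(pd.DataFrame({"F": y}), _one_hot(parts, 2),
                        part_labels=["a", "b"], reference="a")
        path_b = next(e for e in est if e.source == "b")
        assert pytest.approx(path_b.estimator, abs=1e-12) == 2.0
        assert pytest.approx(path_b.se, rel=1e-9) == np.sqrt(0.5)
        assert pytest.approx(path_b.cr, rel=1e-9) == 2.0 / np.sqrt(0.5)
        assert pytest.approx(path_b.p, rel=1e-6) == 0.1055728

    def test_matches_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            parts = rng.integers(0, 9, size=50)
            while len(np.unique(parts)) < 9:
                parts = rng.integers(0, 9, size=50)
            y = rng.standard_normal(50)
            P = _one_hot(parts, 9)
            labels = [f"pp_{i+1}" for i in range(9)]
            est = fit_paths(pd.DataFrame({"F": y}), P, part_labels=labels)
            beta, se, dof = _brute_force_ols(y, P[:, :8])  # reference = pp_9
            assert dof == 50 - 9
            for i in range(8):
                e = next(x for x in est if x.source == labels[i])
                assert pytest.approx(e.estimator, abs=1e-8) == beta[i + 1]
                assert pytest.approx(e.se, abs=1e-8) == se[i + 1]
                p_oracle = 2 * stats.t.sf(abs(beta[i + 1] / se[i + 1]), dof)
                assert pytest.approx(e.p, abs=1e-10) == p_oracle

    def test_all_parts_receive_estimates_via_relevel(self):
        rng = np.random.default_rng(8)
        parts = np.repeat(np.arange(9), 10)
        y = rng.standard_normal(len(parts))
        est = fit_paths(pd.DataFrame({"FA": y, "FB": y * 2}), _one_hot(parts, 9))
        assert len(est) == 18
        assert {e.source for e in est} == {str(i) for i in range(9)}
        assert all(e.estimable for e in est)

    def test_exact_fit_flags_degenerate_ratio(self):
        parts = np.repeat(np.arange(3), 5)
        y = np.array([0.0, 1.0, 2.0])[parts]  # exact function of the part
        est = fit_paths(pd.DataFrame({"F": y}), _one_hot(parts, 3))
        assert all(e.degenerate for e in est)
        nonref = [e for e in est if e.source != "2"]
        assert [pytest.approx(e.estimator, abs=1e-10) for e in nonref] == [-2.0, -1.0]

    def test_empty_part_flagged_not_estimable(self):
        parts = np.repeat([0, 1, 2, 3, 4, 5, 6, 7], 8)  # part 8 unobserved
        y = np.random.default_rng(0).standard_normal(len(parts))
        est = fit_paths(pd.DataFrame({"F": y}), _one_hot(parts, 9))
        missing = [e for e in est if e.source == "8"]
        assert missing and not missing[0].estimable

    def test_non_one_hot_design_rejected(self):
        P = np.ones((20, 3))
        with pytest.raises(ValueError, match="one-hot"):
            fit_paths(pd.DataFrame({"F": np.zeros(20)}), P)


class TestExtractRelations:
    def test_reference_table_yields_fourteen_relations(self):
        rel = extract_relations(D.reference_path_estimates(), alpha=0.05)
        assert len(rel.relations) == 14

    def test_leaf_part_has_exactly_two_relations(self):
        rel = extract_relations(D.reference_path_estimates(), alpha=0.05)
        leaf = [(s, t, g) for s, t, g in rel.relations if s == "pp_4"]
        assert sorted(t for _, t, _ in leaf) == ["FA", "FC"]
        signs = {t: g for _, t, g in leaf}
        assert signs == {"FA": "positive", "FC": "negative"}

    def test_zero_alpha_empty(self):
        assert extract_relations(D.reference_path_estimates(), alpha=0.0).relations == []

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_alpha(self, a1, a2):
        lo, hi = sorted([a1, a2])
        est = D.reference_path_estimates()
        r_lo = set(extract_relations(est, alpha=lo).relations)
        r_hi = set(extract_relations(est, alpha=hi).relations)
        assert r_lo <= r_hi


class TestInterpretSign:
    def test_positive_negative_and_neutral_narratives(self):
        pos = PathEstimate("pp_2", "FA", 0.819, 0.119, 6.908, 0.001)
        neg = PathEstimate("pp_2", "FC", -0.360, 0.078, -4.611, 0.001)
        nil = PathEstimate("pp_1", "FB", 0.0, 0.1, 0.0, 1.0)
        assert "increases the improved" in interpret_sign(pos)
        assert "decreases the degree" in interpret_sign(neg)
        assert "no association" in interpret_sign(nil)
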