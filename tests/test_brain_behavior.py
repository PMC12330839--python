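"""PCA elbow, residualization, CCA and permutation inference."""

import numpy as np
import pandas as pd
import pytest

from langasym.brain_behavior import (
    BrainBehaviorError,
    PermutationCCA,
    cca_fit,
    elbow_point,
    pca_reduce,
    permutation_inference,
    residualize,
)


class TestElbow:
    def test_worked_variance_curve(self):
        assert elbow_point(np.array([50.0, 30, 5, 4, 3, 2])) == 2

    def test_flat_curve_retains_one_with_warning(self):
        with pytest.warns(UserWarning, match="elbow undefined"):
            assert elbow_point(np.full(6, 1 / 6)) == 1

    def test_two_components_retains_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert elbow_point(np.array([0.9, 0.1])) == 1


class TestPCAReduce:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=100)
        feats = pd.DataFrame({"a": x, "b": 2 * x + 1})
        with pytest.warns(UserWarning):
            scores, evr, retained = pca_reduce(feats)
        assert evr[0] == pytest.approx(1.0)
        assert retained == 1
        assert scores.shape == (100, 1)

    def test_constant_variable_named(self, rng):
        feats = pd.DataFrame({"a": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.raises(BrainBehaviorError, match="flat"):
            pca_reduce(feats)

    def test_override_component_count(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 6)))
        scores, _, retained = pca_reduce(feats, n_components=3)
        assert retained == 3 and scores.shape[1] == 3


class TestResidualize:
    def test_exact_linear_function_removed(self, rng):
        age = rng.uniform(18, 88, 40)
        table = pd.DataFrame({"v": 3.0 * age - 7.0})
        res = residualize(table, pd.DataFrame({"age": age}))
        assert np.abs(res["v"]).max() < 1e-9

    def test_orthogonal_column_only_demeaned(self, rng):
        age = np.tile([1.0, -1.0], 20)
        v = np.tile([1.0, 1.0, -1.0, -1.0], 10) + 5.0
        res = residualize(pd.DataFrame({"v": v}), pd.DataFrame({"age": age}))
        assert np.allclose(res["v"], v - v.mean())

    def test_matches_normal_equations_oracle(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0, 7.0]})
        cov = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0]})
        design = np.column_stack([np.ones(4), cov["age"]])
        beta = np.linalg.solve(design.T @ design, design.T @ table["v"])
        expected = table["v"] - design @ beta
        res = residualize(table, cov)
        assert np.allclose(res["v"], expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 60
        cov = pd.DataFrame(
            {"age": rng.uniform(18, 88, n), "sex": rng.choice(["F", "M"], n),
             "mmse": rng.integers(24, 31, n)}
        )
        table = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        res = residualize(table, cov)
        assert np.abs(res.to_numpy().sum(axis=0)).max() < 1e-8
        assert np.abs(cov["age"].to_numpy() @ res.to_numpy()).max() < 1e-7

    def test_missing_covariates_listed(self):
        cov = pd.DataFrame({"age": [20.0, np.nan]}, index=["s0", "s1"])
        with pytest.raises(BrainBehaviorError, match="s1"):
            residualize(pd.DataFrame({"v": [1.0, 2.0]}, index=["s0", "s1"]), cov)


class TestCCA:
    def test_univariate_equals_absolute_pearson(self, rng):
        x = rng.normal(size=300)
        y = -0.4 * x + rng.normal(size=300)
        r = cca_fit(pd.DataFrame({"x": x}), pd.DataFrame({"y": y})).correlations[0]
        assert r == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-12)

    def test_invertible_map_gives_unit_correlations(self, rng):
        x = pd.DataFrame(rng.normal(size=(80, 3)))
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        y = pd.DataFrame(x.to_numpy() @ a)
        assert np.allclose(cca_fit(x, y).correlations, 1.0, atol=1e-10)

    def test_affine_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(120, 4)))
        y = pd.DataFrame(rng.normal(size=(120, 3)))
        r0 = cca_fit(x, y).correlations
        ax = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        by = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        r1 = cca_fit(
            pd.DataFrame(x.to_numpy() @ ax + 7.0),
            pd.DataFrame(y.to_numpy() @ by - 3.0),
        ).correlations
        assert np.allclose(r0, r1, atol=1e-10)

    def test_mode_orthogonality_and_ordering(self, rng):
        x = pd.DataFrame(rng.normal(size=(100, 4)))
        y = pd.DataFrame(rng.normal(size=(100, 4)))
        res = cca_fit(x, y)
        assert np.all(np.diff(res.correlations) <= 1e-12)
        for scores in (res.x_scores, res.y_scores):
            c = np.corrcoef(scores.to_numpy(), rowvar=False)
            assert np.abs(c - np.eye(c.shape[0])).max() < 1e-8
        assert np.all(np.abs(res.x_loadings.to_numpy()) <= 1 + 1e-12)

    def test_rank_deficiency_named(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=50)})
        x["dup"] = x["a"] * 2
        y = pd.DataFrame(rng.normal(size=(50, 2)))
        with pytest.raises(BrainBehaviorError, match="dup|a"):
            cca_fit(x, y)

    def test_sklearn_cross_check(self, rng):
        """First canonical correlation agrees with scikit-learn's iterative
        CCA on a well-conditioned problem."""
        from sklearn.cross_decomposition import CCA as SkCCA

        x = rng.normal(size=(200, 3))
        y = 0.5 * x @ rng.normal(size=(3, 3)) + rng.normal(size=(200, 3))
        r = cca_fit(pd.DataFrame(x), pd.DataFrame(y)).correlations[0]
        sk = SkCCA(n_components=1, max_iter=2000).fit(x, y)
        u, v = sk.transform(x, y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert r == pytest.approx(r_sk, abs=1e-6)


class TestPermutationInference:
    def test_perfect_correlation_attains_minimal_p(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)))
        y = pd.DataFrame(x.to_numpy() @ (rng.normal(size=(3, 3)) + 2 * np.eye(3)))
        res = permutation_inference(x, y, n_perm=199, seed=5)
        assert res.p_values[0] == pytest.approx(1.0 / 200.0)
        assert res.p_fwer[0] == pytest.approx(1.0 / 200.0)

    def test_seeded_determinism(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 3)))
        y = pd.DataFrame(rng.normal(size=(50, 3)))
        a = permutation_inference(x, y, n_perm=150, seed=42)
        b = permutation_inference(x, y, n_perm=150, seed=42)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.p_fwer, b.p_fwer)

    def test_fwer_monotone_and_dominates_uncorrected_mode1(self, rng):
        x = pd.DataFrame(rng.normal(size=(80, 4)))
        y = pd.DataFrame(rng.normal(size=(80, 4)))
        res = permutation_inference(x, y, n_perm=200, seed=3)
        assert np.all(np.diff(res.p_fwer) >= -1e-12)
        assert res.p_fwer[0] >= res.p_values[0] - 1e-12

    def test_low_permutation_count_warns(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 2)))
        y = pd.DataFrame(rng.normal(size=(30, 2)))
        with pytest.warns(UserWarning, match="resolution"):
            permutation_inference(x, y, n_perm=50, seed=0)

    def test_estimator_wrapper(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)))
        y = pd.DataFrame(rng.normal(size=(60, 2)))
        est = PermutationCCA(n_perm=120, random_state=1).fit(x, y)
        assert est.correlations_.shape == (2,)
        assert est.p_fwer_.shape == (2,)
        assert est.get_params()["n_perm"] == 120
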