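"""Gradient chain: correlation, sparsification, affinity, embedding,
alignment, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from langasym.gradients import (
    DegenerateEmbeddingWarning,
    GradientError,
    GradientPipeline,
    build_group_reference,
    compute_connectivity,
    diffusion_embed,
    embed_connectivity,
    minmax_normalize,
    normalized_angle,
    procrustes_align,
    sparsify_rows,
)


class TestConnectivity:
    def test_pearson_values(self):
        ts = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0]})
        c = compute_connectivity(ts)
        assert c.loc["a", "a"] == pytest.approx(1.0)
        assert c.loc["a", "b"] == pytest.approx(0.5)

    def test_anticorrelated_series(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        ts = pd.DataFrame({"a": x, "b": -x})
        assert compute_connectivity(ts).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_region_named(self):
        ts = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(GradientError, match="flat"):
            compute_connectivity(ts)

    def test_too_few_timepoints(self):
        ts = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(GradientError, match="timepoints"):
            compute_connectivity(ts)


class TestSparsify:
    def test_density_one_keeps_offdiagonal(self, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        out = sparsify_rows(m, density=1.0)
        off = ~np.eye(6, dtype=bool)
        assert np.array_equal(out[off], m[off])
        assert np.all(np.diag(out) == 0)

    def test_top_fraction_by_signed_value(self):
        row = np.array([5.0, 4, 3, 2, 1, 0, -1, -2, -3, -4])
        m = np.zeros((11, 11))
        m[0, 1:] = row
        m[1:, 0] = row
        out = sparsify_rows(m, density=0.2)
        assert set(out[0, 1:][out[0, 1:] != 0]) == {5.0, 4.0}

    def test_ties_at_threshold_kept(self):
        m = np.ones((5, 5))
        out = sparsify_rows(m, density=0.4)
        off = ~np.eye(5, dtype=bool)
        assert np.all(out[off] == 1.0)

    def test_invalid_density(self):
        with pytest.raises(GradientError):
            sparsify_rows(np.eye(3), density=0.0)


class TestNormalizedAngle:
    def test_canonical_angles(self):
        m = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        a = normalized_angle(m)
        assert a[0, 1] == pytest.approx(1.0)    # identical rows
        assert a[0, 2] == pytest.approx(0.5)    # orthogonal rows
        assert a[0, 3] == pytest.approx(0.0)    # antipodal rows

    def test_zero_row_rejected(self):
        m = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(GradientError, match="all-zero"):
            normalized_angle(m)

    def test_bounds_and_symmetry(self, rng):
        m = rng.normal(size=(10, 10))
        a = normalized_angle(m)
        assert np.all((a >= 0) & (a <= 1))
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)


class TestDiffusionEmbed:
    def test_two_block_affinity_separates_blocks(self):
        n = 10
        w = np.full((n, n), 0.2)
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        comps, evals, var = diffusion_embed(w, n_components=3)
        g1 = comps[:, 0]
        assert np.all(np.sign(g1[:5]) == np.sign(g1[0]))
        assert np.all(np.sign(g1[5:]) == -np.sign(g1[0]))
        assert np.all(np.diff(evals) <= 1e-12)

    def test_permutation_equivariance(self, rng):
        w = rng.uniform(0.1, 1.0, size=(12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        perm = rng.permutation(12)
        c1, _, _ = diffusion_embed(w, n_components=2)
        c2, _, _ = diffusion_embed(w[np.ix_(perm, perm)], n_components=2)
        for k in range(2):
            dot = abs(np.dot(c1[perm, k], c2[:, k]))
            norm = np.linalg.norm(c1[:, k]) * np.linalg.norm(c2[:, k])
            assert dot == pytest.approx(norm, rel=1e-8)

    def test_constant_affinity_flagged_degenerate(self):
        w = np.ones((6, 6))
        with pytest.warns(DegenerateEmbeddingWarning):
            comps, evals, _ = diffusion_embed(w, n_components=2)
        assert abs(evals[0]) < 1e-10

    def test_variance_fractions_are_a_distribution(self, rng):
        w = rng.uniform(0.2, 1.0, size=(15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        _, _, var = diffusion_embed(w, n_components=5)
        assert np.all(var >= 0)
        assert var.sum() <= 1 + 1e-12
        assert np.all(np.diff(var) <= 1e-12)

    def test_asymmetric_affinity_rejected(self, rng):
        with pytest.raises(GradientError, match="symmetric"):
            diffusion_embed(rng.uniform(size=(4, 4)))


class TestProcrustes:
    def test_identity_when_already_aligned(self, rng):
        x = rng.normal(size=(20, 4))
        assert np.allclose(procrustes_align(x, x), x)

    def test_recovers_sign_flip(self, rng):
        ref = rng.normal(size=(20, 4))
        flipped = ref.copy()
        flipped[:, 0] *= -1
        assert np.allclose(procrustes_align(flipped, ref), ref, atol=1e-10)

    def test_recovers_random_orthogonal_mix(self, rng):
        ref = rng.normal(size=(30, 5))
        q = ortho_group.rvs(5, random_state=3)
        assert np.allclose(procrustes_align(ref @ q, ref), ref, atol=1e-8)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(GradientError, match="mismatch"):
            procrustes_align(rng.normal(size=(5, 2)), rng.normal(size=(5, 3)))


class TestMinMax:
    def test_worked_example(self):
        assert np.allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])), [0, 50, 100])

    def test_range_and_affine_invariance(self, rng):
        g = rng.normal(size=25)
        out = minmax_normalize(g)
        assert out.min() == 0.0 and out.max() == 100.0
        assert np.allclose(minmax_normalize(3.0 * g - 7.0), out)

    def test_constant_gradient_rejected(self):
        with pytest.raises(GradientError, match="constant"):
            minmax_normalize(np.ones(5))


class TestGroupReference:
    def test_single_subject_reference_matches_subject(self, rng):
        w = rng.normal(size=(60, 20))
        conn = pd.DataFrame(np.corrcoef(w, rowvar=False))
        ref, _, _ = build_group_reference([conn], n_components=3)
        own, _, _ = embed_connectivity(conn, n_components=3)
        r = np.corrcoef(ref[:, 0], own[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_identical_subjects_reference(self, rng):
        w = rng.normal(size=(60, 20))
        conn = pd.DataFrame(np.corrcoef(w, rowvar=False))
        ref1, _, _ = build_group_reference([conn], n_components=3)
        ref3, _, _ = build_group_reference([conn] * 3, n_components=3)
        assert np.allclose(ref1, ref3)

    def test_anchor_orientation(self, rng):
        w = rng.normal(size=(80, 20))
        conn = pd.DataFrame(np.corrcoef(w, rowvar=False))
        ref, _, _ = build_group_reference([conn], n_components=3, anchor_regions=[0, 1, 2])
        assert ref[[0, 1, 2], 0].mean() > 0


class TestPipelineEstimator:
    def test_recovers_planted_gradient(self, small_cohort):
        gt = small_cohort.ground_truth
        mean_load = gt.loadings.mean(axis=0)
        anchors = np.argsort(mean_load.to_numpy())[-3:].tolist()
        pipe = GradientPipeline(anchor_regions=anchors)
        g1 = pipe.fit_transform(small_cohort.timeseries)
        assert (g1.min(axis=1) == 0).all()
        assert (g1.max(axis=1) == 100).all()
        rs = [
            np.corrcoef(g1.loc[s], gt.loadings.loc[s])[0, 1] for s in g1.index
        ]
        assert np.median(rs) > 0.85

    def test_sklearn_params_roundtrip(self):
        pipe = GradientPipeline(density=0.2, n_components=5)
        params = pipe.get_params()
        assert params["density"] == 0.2
        clone = GradientPipeline(**params)
        assert clone.get_params() == params
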