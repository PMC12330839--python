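"""Factor-smooth trajectory model: exact linear truth, interaction test,
FDR, demeaned asymmetry curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

from langasym.gam import FactorSmoothGAM, GamError, build_basis
from langasym.simulate import generate_pair_long_table
from langasym.trajectories import (
    TrajectoryError,
    asymmetry_trajectory,
    bh_fdr,
    fit_region_gamm,
)


@pytest.fixture(scope="module")
def linear_fit():
    data = generate_pair_long_table(
        120,
        lambda a: 1.0 + 0.05 * a,
        lambda a: 2.0 - 0.03 * a,
        subject_sd=0.0,
        noise_sd=0.0,
        seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return data, FactorSmoothGAM().fit(data)


class TestFit:
    def test_noiseless_linear_truth_recovered_exactly(self, linear_fit):
        data, model = linear_fit
        grid = np.linspace(data["age"].min(), data["age"].max(), 100)
        assert np.abs(model.predict_hemisphere(grid, "L") - (1.0 + 0.05 * grid)).max() < 1e-6
        assert np.abs(model.predict_hemisphere(grid, "R") - (2.0 - 0.03 * grid)).max() < 1e-6

    def test_identical_hemispheres_give_null_difference(self):
        data = generate_pair_long_table(
            150, lambda a: 5 + np.sin(a / 20), lambda a: 5 + np.sin(a / 20),
            subject_sd=0.5, noise_sd=0.5, seed=6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = FactorSmoothGAM().fit(data)
        grid = np.linspace(data["age"].min(), data["age"].max(), 50)
        curve = m.asymmetry_curve(grid)
        # curve is pure noise: small relative to the hemispheric signal
        assert np.abs(curve["asymmetry"]).max() < 0.5
        assert ((curve["lo"] <= 0) & (curve["hi"] >= 0)).mean() > 0.8

    def test_default_basis_size_is_six(self, linear_fit):
        _, model = linear_fit
        assert model.basis_.n_basis == 6
        assert model.k == 6

    def test_missing_hemisphere_rejected(self):
        data = generate_pair_long_table(
            30, lambda a: a, lambda a: a, seed=0
        ).query("hemisphere == 'L'")
        with pytest.raises(GamError, match="left and one right"):
            FactorSmoothGAM().fit(data)

    def test_aliased_covariate_named(self):
        data = generate_pair_long_table(60, lambda a: a, lambda a: a, seed=0)
        data["sex"] = data["site"].map({1: "F", 2: "M", 3: "M"})
        data["site"] = data["sex"]  # sex and site perfectly aliased
        with pytest.raises(GamError, match="aliased"):
            FactorSmoothGAM().fit(data)


class TestInteractionTest:
    def test_planted_divergence_detected(self):
        data = generate_pair_long_table(
            300, lambda a: 5 + 0.05 * (a - 50), lambda a: 5 - 0.05 * (a - 50),
            subject_sd=1.0, noise_sd=1.0, seed=9,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = FactorSmoothGAM().fit(data)
        _, _, p = m.interaction_test()
        assert p < 1e-4

    def test_degenerate_zero_difference_gives_p_one(self):
        data = generate_pair_long_table(
            60, lambda a: 2 + 0.1 * a, lambda a: 2 + 0.1 * a,
            subject_sd=0.0, noise_sd=0.0, seed=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = FactorSmoothGAM().fit(data)
        stat, _, p = m.interaction_test()
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == 1.0

    def test_hemisphere_relabel_preserves_p_and_negates_curve(self):
        data = generate_pair_long_table(
            120, lambda a: 5 + 0.02 * a, lambda a: 5 - 0.01 * a,
            subject_sd=0.5, noise_sd=0.5, seed=12,
        )
        swapped = data.copy()
        swapped["hemisphere"] = swapped["hemisphere"].map({"L": "R", "R": "L"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = FactorSmoothGAM().fit(data)
            m2 = FactorSmoothGAM().fit(swapped)
        assert m1.interaction_test()[2] == pytest.approx(m2.interaction_test()[2], rel=1e-9)
        grid = np.linspace(data["age"].min(), data["age"].max(), 40)
        c1 = m1.asymmetry_curve(grid)["asymmetry"]
        c2 = m2.asymmetry_curve(grid)["asymmetry"]
        assert np.allclose(c1, -c2, atol=1e-6)


class TestBHFDR:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_trivial_cases(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= p)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(TrajectoryError):
            bh_fdr([0.5, 1.5])


class TestAsymmetryCurve:
    def test_constant_offset_removed_by_demeaning(self):
        data = generate_pair_long_table(
            100, lambda a: 3 + np.sin(a / 25) + 2.0, lambda a: 3 + np.sin(a / 25),
            subject_sd=0.0, noise_sd=0.0, seed=4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = FactorSmoothGAM().fit(data)
        grid = np.linspace(data["age"].min(), data["age"].max(), 60)
        curve = m.asymmetry_curve(grid)["asymmetry"]
        assert np.abs(curve).max() < 1e-6

    def test_grid_outside_support_rejected(self, linear_fit):
        _, model = linear_fit
        with pytest.raises(GamError, match="extrapolation"):
            model.asymmetry_curve(np.linspace(0, 120, 10))

    def test_fit_region_gamm_wrapper(self):
        data = generate_pair_long_table(
            80, lambda a: 1 + 0.02 * a, lambda a: 1 - 0.02 * a,
            subject_sd=0.5, noise_sd=0.5, seed=2,
        )
        data["pair_id"] = "pairX"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_region_gamm(data)
        assert fit.pair_id == "pairX"
        grid = np.linspace(data["age"].min(), data["age"].max(), 30)
        curve = asymmetry_trajectory(fit, grid)
        assert list(curve.columns) == ["age", "asymmetry", "lo", "hi"]
        assert (curve["hi"] >= curve["lo"]).all()
        lo_end, hi_end = fit.smooth_endpoints
        assert lo_end == pytest.approx(curve["asymmetry"].iloc[0])
        assert hi_end == pytest.approx(curve["asymmetry"].iloc[-1])


def test_basis_respects_requested_size(rng):
    ages = rng.uniform(18, 88, 200)
    for k in (4, 6, 9):
        basis = build_basis(ages, k)
        assert basis.n_basis == k
        assert basis.evaluate(ages).shape == (200, k - 1)
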