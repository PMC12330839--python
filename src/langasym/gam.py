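"""Factor-smooth penalized-spline model for hemispheric age trajectories.

The model, per homotopic pair, on a long table with two rows (left, right)
per subject:

    value = intercept + hemisphere + sex + site
            + f(age)                      (shared smooth)
            + f_delta(age) * [hemi == L]  (difference smooth)
            + subject random intercept + noise

Both smooths are cubic B-spline bases (k basis functions, knots at age
quantiles) with a second-derivative curvature penalty and a sum-to-zero
identifiability constraint; the subject intercepts are a ridge-penalized
dummy block.  All three smoothing parameters (shared curvature, difference
curvature, intercept precision) are chosen by REML through the mixed-model
representation of penalized regression.  The Hemisphere x Age interaction
is tested exactly through the paired within-subject contrast (see
:meth:`FactorSmoothGAM.interaction_test`).

With one observation per subject and hemisphere the subject intercept and
the residual are separated only by the within-subject (between-hemisphere)
contrast; the model is identified, but the two variance components should
not be interpreted individually on such data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator


class GamError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# spline basis


@dataclass
class SplineBasis:
    """Cubic B-spline basis with a curvature penalty and a sum-to-zero
    constraint estimated from the training ages."""

    knots: np.ndarray          # full knot vector (boundary knots repeated)
    constraint: np.ndarray     # k x (k-1) null-space transform
    lo: float
    hi: float

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 4

    def raw(self, ages: np.ndarray) -> np.ndarray:
        a = np.clip(np.asarray(ages, dtype=float), self.lo, self.hi)
        design = BSpline.design_matrix(a, self.knots, 3).toarray()
        return design

    def evaluate(self, ages: np.ndarray) -> np.ndarray:
        """Constrained basis (k-1 columns)."""
        return self.raw(ages) @ self.constraint

    def penalty(self) -> np.ndarray:
        """Constrained curvature penalty: S_ij = int B_i'' B_j'' da."""
        k = self.n_basis
        s = np.zeros((k, k))
        # two-point Gauss-Legendre per inter-knot interval is exact: second
        # derivatives of cubic splines are piecewise linear
        breaks = np.unique(self.knots)
        gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        eye = np.eye(k)
        for a, b in zip(breaks[:-1], breaks[1:]):
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            pts = mid + half * gl_x
            d2 = np.column_stack(
                [BSpline(self.knots, eye[:, j], 3)(pts, nu=2) for j in range(k)]
            )
            s += half * d2.T @ d2
        return self.constraint.T @ s @ self.constraint


def build_basis(ages: np.ndarray, k: int = 6) -> SplineBasis:
    """Basis with ``k`` cubic B-spline functions, interior knots at age
    quantiles, and a sum-to-zero constraint over the supplied ages."""
    if k < 4:
        raise GamError("cubic spline basis needs k >= 4")
    a = np.asarray(ages, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise GamError("degenerate age range")
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(a, qs)
    else:
        interior = np.empty(0)
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    design = BSpline.design_matrix(a, knots, 3).toarray()
    colsum = design.sum(axis=0, keepdims=True)
    # orthonormal basis of the null space of the column-sum constraint
    _, _, vt = np.linalg.svd(colsum, full_matrices=True)
    constraint = vt[1:].T
    return SplineBasis(knots=knots, constraint=constraint, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# fitting


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype("category"), prefix=prefix, drop_first=True)
    return d.astype(float)


class FactorSmoothGAM(BaseEstimator):
    """Hemispheric factor-smooth additive model with subject intercepts.

    Parameters
    ----------
    k : int
        Number of B-spline basis functions per smooth (before the
        sum-to-zero constraint removes one).
    covariates : tuple of str
        Categorical nuisance covariates taken from the data table.
    value_col, age_col, hemi_col, subject_col : str
        Column names of the long input table.

    Fitted attributes (after :meth:`fit`)
    -------------------------------------
    coef_ : ndarray, stacked coefficients
    coef_cov_ : ndarray, Bayesian covariance of ``coef_``
    lambdas_ : dict, REML smoothing parameters
    edf_diff_ : float, effective df of the difference smooth
    sigma2_ : float, residual variance
    converged_ : bool
    """

    _HEMIS = ("L", "R")

    def __init__(
        self,
        k: int = 6,
        covariates: tuple[str, ...] = ("sex", "site"),
        value_col: str = "value",
        age_col: str = "age",
        hemi_col: str = "hemisphere",
        subject_col: str = "subject_id",
    ):
        self.k = k
        self.covariates = covariates
        self.value_col = value_col
        self.age_col = age_col
        self.hemi_col = hemi_col
        self.subject_col = subject_col

    # -- design ------------------------------------------------------------

    def _validate(self, data: pd.DataFrame) -> pd.DataFrame:
        need = {self.value_col, self.age_col, self.hemi_col, self.subject_col}
        need |= set(self.covariates)
        missing = need - set(data.columns)
        if missing:
            raise GamError(f"input table is missing columns: {sorted(missing)}")
        counts = data.groupby([self.subject_col, self.hemi_col]).size()
        if (counts != 1).any() or (
            data.groupby(self.subject_col)[self.hemi_col].nunique() != 2
        ).any():
            raise GamError(
                "need exactly one left and one right observation per subject"
            )
        return data.reset_index(drop=True)

    def _fixed_design(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {"intercept": np.ones(len(data))}
        cols["hemiL"] = (data[self.hemi_col] == "L").astype(float).to_numpy()
        fixed = pd.DataFrame(cols)
        for cov in self.covariates:
            d = _dummies(data[cov], cov)
            for c in d.columns:
                fixed[c] = d[c].to_numpy()
        x = fixed.to_numpy()
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(x, pivoting=True)
            aliased = [fixed.columns[j] for j in piv[rank:]]
            raise GamError(f"singular fixed-effect design; aliased terms: {aliased}")
        return fixed

    _RHO_BOUND = 18.0  # |log lambda| cap, keeps the system well conditioned

    def fit(self, data: pd.DataFrame, y=None) -> "FactorSmoothGAM":
        """Fit by REML.

        The subject-intercept block is absorbed analytically: with exactly
        two observations per subject the dummy cross-product is ``2 I``, so
        each REML evaluation reduces, via a Schur complement, to dense
        algebra in the small fixed+smooth coefficient space.
        """
        data = self._validate(data)
        yv = data[self.value_col].to_numpy(dtype=float)
        ages = data[self.age_col].to_numpy(dtype=float)
        self.basis_ = build_basis(ages, self.k)
        fixed = self._fixed_design(data)
        self.fixed_names_ = list(fixed.columns)
        b_shared = self.basis_.evaluate(ages)
        hemi = (data[self.hemi_col] == "L").to_numpy(dtype=float)
        b_diff = b_shared * hemi[:, None]
        subjects = pd.Categorical(data[self.subject_col])
        self.subject_levels_ = list(subjects.categories)
        codes = subjects.codes
        n_subj = len(self.subject_levels_)

        x = np.hstack([fixed.to_numpy(), b_shared, b_diff])
        p_fixed = fixed.shape[1]
        p_sm = b_shared.shape[1]
        p_x = x.shape[1]
        self._slices = {
            "fixed": slice(0, p_fixed),
            "shared": slice(p_fixed, p_fixed + p_sm),
            "diff": slice(p_fixed + p_sm, p_x),
        }
        s_pen = self.basis_.penalty()
        s_pen = s_pen / np.mean(np.diag(s_pen))  # unit scale for lambda
        ev = np.linalg.eigvalsh(s_pen)
        pos = ev[ev > ev.max() * 1e-10]
        rank_pen, lpd_pen = len(pos), float(np.sum(np.log(pos)))
        s_embedded = []
        for name in ("shared", "diff"):
            s_full = np.zeros((p_x, p_x))
            sl = self._slices[name]
            s_full[sl, sl] = s_pen
            s_embedded.append(s_full)

        xtx = x.T @ x
        xty = x.T @ yv
        yty = float(yv @ yv)
        # subject-aggregated quantities (Z'Z = 2I with two rows per subject)
        b_mat = np.zeros((n_subj, p_x))
        np.add.at(b_mat, codes, x)
        b_mat = b_mat.T                       # p_x x n_subj
        zty = np.bincount(codes, weights=yv, minlength=n_subj)
        bbt = b_mat @ b_mat.T
        bzty = b_mat @ zty

        n = len(yv)
        m_p = p_x - 2 * rank_pen
        var_y = max(np.var(yv), 1e-300)
        bound = self._RHO_BOUND

        def pieces(rho: np.ndarray):
            lam1, lam2, lam3 = np.exp(np.clip(rho, -bound, bound))
            denom = 2.0 + lam3
            h_eff = xtx + lam1 * s_embedded[0] + lam2 * s_embedded[1] - bbt / denom
            chol = cho_factor(h_eff, lower=True)
            theta_x = cho_solve(chol, xty - bzty / denom)
            theta_b = (zty - b_mat.T @ theta_x) / denom
            d = max(yty - float(theta_x @ xty) - float(theta_b @ zty), 0.0)
            sigma2 = max(d / (n - m_p), 1e-13 * var_y)
            logdet_h = n_subj * np.log(denom) + 2.0 * np.sum(
                np.log(np.diag(chol[0]))
            )
            r1, r2, r3 = np.clip(rho, -bound, bound)
            logdet_s = (
                rank_pen * r1 + lpd_pen + rank_pen * r2 + lpd_pen + n_subj * r3
            )
            return chol, theta_x, theta_b, sigma2, denom, logdet_h, logdet_s

        def reml(rho: np.ndarray) -> float:
            try:
                _, _, _, sigma2, _, logdet_h, logdet_s = pieces(rho)
            except np.linalg.LinAlgError:
                return 1e12
            return (
                (n - m_p) * (1.0 + np.log(2.0 * np.pi * sigma2))
                + logdet_h
                - logdet_s
            ) / 2.0

        res = optimize.minimize(
            reml,
            x0=np.zeros(3),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-7},
        )
        self.converged_ = bool(res.success)
        if not res.success:
            warnings.warn(
                "REML optimization did not report convergence; using best "
                "point found",
                ConvergenceWarning,
                stacklevel=2,
            )
        rho = np.clip(res.x, -bound, bound)
        self.lambdas_ = dict(zip(("shared", "diff", "subject"), np.exp(rho)))
        chol, theta_x, theta_b, sigma2, denom, _, _ = pieces(rho)
        self.sigma2_ = sigma2
        e_mat = cho_solve(chol, np.eye(p_x))
        self.coef_ = theta_x
        self.subject_effects_ = theta_b
        self.coef_cov_ = e_mat * sigma2
        # per-coefficient effective df: diag of (H^-1 C'C) over the
        # fixed+smooth block, using the Schur-complement identity
        edf_x = np.sum(e_mat * (xtx - bbt / denom), axis=1)
        tr_beb = float(np.sum(e_mat * bbt))
        edf_subj = 2.0 * (n_subj / denom + tr_beb / denom**2) - tr_beb / denom
        self.edf_ = float(edf_x.sum() + edf_subj)
        self.edf_diff_ = float(edf_x[self._slices["diff"]].sum())
        self.n_obs_ = n
        self.age_support_ = (self.basis_.lo, self.basis_.hi)
        # per-subject within-pair differences for the exact interaction test
        wide = data.pivot_table(
            index=self.subject_col, columns=self.hemi_col, values=self.value_col
        )
        age_by_subj = data.groupby(self.subject_col)[self.age_col].first()
        self._paired_diff = (
            age_by_subj.loc[wide.index].to_numpy(dtype=float),
            (wide["L"] - wide["R"]).to_numpy(dtype=float),
        )
        return self

    # -- inference & prediction -------------------------------------------

    def interaction_test(self) -> tuple[float, float, float]:
        """Exact F-test that the hemispheric difference smooth is constant.

        With one left and one right observation per subject, the
        within-subject difference ``d_i = y_iL - y_iR`` cancels the subject
        intercept, the shared age smooth and all subject-level covariates,
        leaving ``d_i = const + f_delta(age_i) + noise``.  The test is the
        classical F-test of the (unpenalized) difference-smooth basis in
        that paired regression — exactly calibrated under Gaussian noise,
        unlike a Wald test referred to a data-selected effective df.

        Returns ``(F_statistic, numerator_df, p_value)``.
        """
        if not hasattr(self, "coef_"):
            raise GamError("model not fitted")
        ages, d = self._paired_diff
        n = len(d)
        bmat = self.basis_.evaluate(ages)
        q = bmat.shape[1]
        if n - q - 1 <= 0:
            raise GamError("too few subjects for the interaction test")
        resid0 = d - d.mean()
        rss0 = float(resid0 @ resid0)
        if rss0 <= 1e-12 * (float(d @ d) + 1.0):
            # hemispheres differ by at most a constant: nothing to test
            return 0.0, float(q), 1.0
        xc = bmat - bmat.mean(axis=0)
        coef, _, _, _ = np.linalg.lstsq(xc, resid0, rcond=None)
        resid1 = resid0 - xc @ coef
        rss1 = float(resid1 @ resid1)
        if rss1 <= 0.0:
            return np.inf, float(q), 0.0
        fstat = max((rss0 - rss1) / q, 0.0) / (rss1 / (n - q - 1))
        p = float(stats.f.sf(fstat, q, n - q - 1)) if fstat > 0 else 1.0
        return float(fstat), float(q), p

    def _check_grid(self, ages: np.ndarray) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        lo, hi = self.age_support_
        if a.min() < lo - 1e-9 or a.max() > hi + 1e-9:
            raise GamError(
                f"age grid [{a.min():g}, {a.max():g}] outside the fitted "
                f"support [{lo:g}, {hi:g}]; no extrapolation"
            )
        return a

    def _prediction_rows(self, ages: np.ndarray, hemisphere: str) -> np.ndarray:
        """Linear-predictor rows at reference covariates (first levels),
        subject intercept 0."""
        a = self._check_grid(ages)
        m = len(a)
        p = len(self.coef_)
        rows = np.zeros((m, p))
        fx = self._slices["fixed"]
        rows[:, fx.start] = 1.0  # intercept
        if hemisphere == "L":
            rows[:, fx.start + 1] = 1.0
        b = self.basis_.evaluate(a)
        rows[:, self._slices["shared"]] = b
        if hemisphere == "L":
            rows[:, self._slices["diff"]] = b
        return rows

    def predict_hemisphere(
        self, ages: np.ndarray, hemisphere: str, se: bool = False
    ):
        """Fitted smooth trajectory of one hemisphere at reference
        covariates."""
        if hemisphere not in self._HEMIS:
            raise GamError("hemisphere must be 'L' or 'R'")
        rows = self._prediction_rows(ages, hemisphere)
        fit = rows @ self.coef_
        if not se:
            return fit
        var = np.einsum("ij,jk,ik->i", rows, self.coef_cov_, rows)
        return fit, np.sqrt(np.maximum(var, 0.0))

    def asymmetry_curve(
        self, ages: np.ndarray, level: float = 0.95
    ) -> pd.DataFrame:
        """Demeaned left-minus-right trajectory with pointwise CI.

        Each hemispheric curve is zero-centered over the grid before
        subtraction, which removes level offsets (including all covariate
        and intercept terms) and isolates shape divergence.
        """
        a = self._check_grid(ages)
        m = len(a)
        center = np.eye(m) - np.ones((m, m)) / m
        rows = center @ (
            self._prediction_rows(a, "L") - self._prediction_rows(a, "R")
        )
        curve = rows @ self.coef_
        var = np.einsum("ij,jk,ik->i", rows, self.coef_cov_, rows)
        half = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(np.maximum(var, 0.0))
        return pd.DataFrame(
            {"age": a, "asymmetry": curve, "lo": curve - half, "hi": curve + half}
        )
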