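"""Brain-behavior coupling: PCA reduction, residualization, permutation CCA.

The brain set (gradient and normalized-volume asymmetries of one trajectory
cluster) is summarized by principal components retained at the elbow of the
cumulative explained-variance curve; both variable sets are residualized on
sex, age and MMSE; canonical correlation analysis links them; and each
mode's significance is assessed by permutation of subject rows with
step-down max-statistic family-wise error control (Wilks-type tail-product
statistic per mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA


class BrainBehaviorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA with elbow selection


def elbow_point(explained_variance: np.ndarray) -> int:
    """Elbow of a variance curve: the point of maximum perpendicular
    distance between the cumulative explained-variance curve and the chord
    joining its first and last points (kneedle-style).

    Returns the 1-based number of components to retain.  A degenerate chord
    (straight-line curve, e.g. isotropic noise) retains 1 with a warning.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.size < 3:
        if ev.size == 0:
            raise BrainBehaviorError("empty variance curve")
        warnings.warn("elbow undefined for < 3 components; retaining 1",
                      UserWarning, stacklevel=2)
        return 1
    cum = np.cumsum(ev)
    x = np.arange(1, ev.size + 1, dtype=float)
    dx, dy = x[-1] - x[0], cum[-1] - cum[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (cum - cum[0])) / norm
    if dist.max() < 1e-9 * max(abs(cum[-1]), 1.0):
        warnings.warn("elbow undefined (variance curve is a straight line); "
                      "retaining 1 component", UserWarning, stacklevel=2)
        return 1
    return int(np.argmax(dist)) + 1


def pca_reduce(
    features: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Standardize, run PCA, and retain components at the elbow.

    Returns ``(scores, explained_variance_ratio, n_retained)``; ``scores``
    holds only the retained components.  ``n_components`` overrides the
    elbow choice when given.
    """
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2:
        raise BrainBehaviorError("need at least 2 variables for PCA")
    if n <= p:
        raise BrainBehaviorError("need more subjects than variables")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [features.columns[i] for i in np.flatnonzero(sd == 0)]
        raise BrainBehaviorError(f"constant variable(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(z)
    evr = pca.explained_variance_ratio_
    retained = n_components if n_components is not None else elbow_point(evr)
    cols = [f"PC{i + 1}" for i in range(retained)]
    return (
        pd.DataFrame(scores[:, :retained], index=features.index, columns=cols),
        evr,
        retained,
    )


# ---------------------------------------------------------------------------
# residualization


def residualize(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove covariate effects from every column by OLS.

    Categorical covariates are dummy-coded; an intercept is always
    included.  Residuals are exactly orthogonal to the design.
    """
    if len(table) != len(covariates):
        raise BrainBehaviorError("table and covariates differ in length")
    na_rows = covariates.isna().any(axis=1)
    if na_rows.any():
        idx = list(covariates.index[na_rows])
        raise BrainBehaviorError(f"missing covariates for subjects: {idx}")
    parts = [np.ones((len(table), 1))]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc":
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            d = pd.get_dummies(s.astype("category"), drop_first=True)
            parts.append(d.to_numpy(dtype=float))
    design = np.hstack(parts)
    y = table.to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.DataFrame(resid, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# CCA


def _qr_full_rank(x: np.ndarray, names, what: str) -> tuple[np.ndarray, np.ndarray]:
    q, r, piv = scipy_qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < x.shape[1]:
        dep = [names[j] for j in piv[rank:]]
        raise BrainBehaviorError(
            f"{what} set is rank deficient; dependent columns: {dep}"
        )
    q2, r2 = np.linalg.qr(x)
    return q2, r2


@dataclass
class CCAResult:
    """Canonical correlations, loadings and (optionally) permutation
    inference for one brain-behavior analysis."""

    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    variance_explained_x: np.ndarray   # percent per mode
    variance_explained_y: np.ndarray
    p_values: np.ndarray | None = None
    p_fwer: np.ndarray | None = None
    n_permutations: int | None = None


def cca_fit(brain: pd.DataFrame, behavior: pd.DataFrame) -> CCAResult:
    """Canonical correlation analysis via the whitened cross-covariance SVD.

    Canonical variates have unit sample variance; loadings are the Pearson
    correlations of each original variable with its set's variate, and a
    mode's "variance explained" within a set is the mean squared loading
    of that set's variables, in percent.
    """
    x = brain.to_numpy(dtype=float)
    y = behavior.to_numpy(dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise BrainBehaviorError("sets differ in subject count")
    p, q = x.shape[1], y.shape[1]
    if n <= p + q:
        raise BrainBehaviorError("need more subjects than total variables")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    qx, rx = _qr_full_rank(xc, list(brain.columns), "brain")
    qy, ry = _qr_full_rank(yc, list(behavior.columns), "behavior")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    m = min(p, q)
    r = np.clip(s[:m], 0.0, 1.0)
    wx = np.linalg.solve(rx, u[:, :m]) * np.sqrt(n - 1)
    wy = np.linalg.solve(ry, vt.T[:, :m]) * np.sqrt(n - 1)
    xs = xc @ wx
    ys = yc @ wy
    def _loadings(orig, scores):
        out = np.zeros((orig.shape[1], m))
        os = orig - orig.mean(axis=0)
        ssd = np.sqrt((os**2).sum(axis=0))
        sc = scores - scores.mean(axis=0)
        scn = np.sqrt((sc**2).sum(axis=0))
        out = (os.T @ sc) / np.outer(ssd, scn)
        return out
    lx = _loadings(x, xs)
    ly = _loadings(y, ys)
    modes = [f"mode{i + 1}" for i in range(m)]
    return CCAResult(
        correlations=r,
        x_weights=wx,
        y_weights=wy,
        x_scores=pd.DataFrame(xs, index=brain.index, columns=modes),
        y_scores=pd.DataFrame(ys, index=behavior.index, columns=modes),
        x_loadings=pd.DataFrame(lx, index=brain.columns, columns=modes),
        y_loadings=pd.DataFrame(ly, index=behavior.columns, columns=modes),
        variance_explained_x=np.mean(lx**2, axis=0) * 100.0,
        variance_explained_y=np.mean(ly**2, axis=0) * 100.0,
    )


def _tail_stats(r: np.ndarray) -> np.ndarray:
    """Wilks-type statistic per mode: -log prod_{j>=k} (1 - r_j^2).

    Larger means stronger; robust to the distribution of the trailing
    modes.
    """
    one_minus = np.clip(1.0 - r**2, 1e-300, 1.0)
    return -np.log(one_minus[::-1]).cumsum()[::-1]


def permutation_inference(
    brain: pd.DataFrame,
    behavior: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> CCAResult:
    """CCA with permutation p-values and step-down max-statistic FWER.

    Subject rows of the behavior set are permuted; each mode k is scored by
    the Wilks tail product over modes >= k.  Uncorrected p-values use each
    mode's own permutation distribution; FWER-corrected p-values compare
    mode k's observed statistic against the permutation maximum over modes
    >= k, with monotonicity enforced across modes (step-down max-T).
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution",
            UserWarning,
            stacklevel=2,
        )
    result = cca_fit(brain, behavior)
    x = brain.to_numpy(dtype=float)
    y = behavior.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    qx, _ = np.linalg.qr(xc)
    qy, _ = np.linalg.qr(yc)
    m = len(result.correlations)
    obs = _tail_stats(result.correlations)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    exceed = np.zeros(m)
    exceed_max = np.zeros(m)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = np.linalg.svd(qx.T @ qy[perm], compute_uv=False)
        t = _tail_stats(np.clip(s[:m], 0.0, 1.0))
        exceed += t >= obs
        # max over modes >= k (suffix maximum) for step-down FWER
        suffix_max = np.maximum.accumulate(t[::-1])[::-1]
        exceed_max += suffix_max >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p_fwer = (1.0 + exceed_max) / (1.0 + n_perm)
    p_fwer = np.maximum.accumulate(p_fwer)  # monotone across modes
    result.p_values = p
    result.p_fwer = p_fwer
    result.n_permutations = n_perm
    return result


class PermutationCCA(BaseEstimator):
    """Estimator wrapper: permutation-validated CCA between two sets.

    Parameters
    ----------
    n_perm : int
        Number of row permutations of the second set.
    random_state : int
        Seed of the permutation stream.

    Fitted attributes mirror :class:`CCAResult` (``correlations_``,
    ``x_loadings_``, ``p_fwer_``, ...).
    """

    def __init__(self, n_perm: int = 1000, random_state: int = 0):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame):
        res = permutation_inference(
            X, Y, n_perm=self.n_perm, seed=self.random_state
        )
        self.result_ = res
        self.correlations_ = res.correlations
        self.x_loadings_ = res.x_loadings
        self.y_loadings_ = res.y_loadings
        self.x_scores_ = res.x_scores
        self.y_scores_ = res.y_scores
        self.variance_explained_x_ = res.variance_explained_x
        self.variance_explained_y_ = res.variance_explained_y
        self.p_values_ = res.p_values
        self.p_fwer_ = res.p_fwer
        return self
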