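"""Subject-level principal connectivity gradients.

The chain implemented here turns a regional BOLD time-series table into the
subject's position of every region along the principal connectivity
gradient (G1, unimodal to transmodal):

1. Pearson correlation across regions;
2. row sparsification keeping each region's top-``density`` connections;
3. normalized-angle affinity between sparsified rows;
4. diffusion-map embedding of the affinity (anisotropic alpha-normalization
   followed by the Markov operator's spectral decomposition);
5. Procrustes alignment of individual embeddings to a group reference;
6. per-subject whole-brain min-max normalization to a 0-100 scale.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class GradientError(ValueError):
    pass


class DegenerateEmbeddingWarning(UserWarning):
    """Embedding has a (near-)zero leading non-trivial eigenvalue."""


def compute_connectivity(timeseries: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between all region time series."""
    x = np.asarray(timeseries, dtype=float)
    if x.shape[0] < 3:
        raise GradientError("need at least 3 timepoints for a correlation matrix")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        cols = list(timeseries.columns)
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise GradientError(f"zero-variance region(s): {bad}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=timeseries.columns, columns=timeseries.columns)


def sparsify_rows(matrix: np.ndarray | pd.DataFrame, density: float = 0.10) -> np.ndarray:
    """Keep each row's top-``density`` off-diagonal connections (by signed
    value), zeroing the rest.  Ties at the threshold are kept; the diagonal
    is excluded from ranking and set to zero.  The result is generally
    asymmetric.
    """
    if not 0.0 < density <= 1.0:
        raise GradientError("density must be in (0, 1]")
    m = np.array(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise GradientError("connectivity matrix must be square")
    out = np.zeros_like(m)
    offdiag_mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = m[i]
        vals = row[offdiag_mask[i]]
        thr = np.quantile(vals, 1.0 - density)
        keep = (row >= thr) & offdiag_mask[i]
        out[i, keep] = row[keep]
    return out


def normalized_angle(matrix: np.ndarray) -> np.ndarray:
    """Normalized-angle affinity between rows: 1 - arccos(cos_sim)/pi.

    Identical rows map to 1, orthogonal rows to 0.5, antipodal rows to 0.
    """
    m = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0).tolist()
        raise GradientError(f"all-zero row(s) {bad}: cosine similarity undefined")
    cos = (m @ m.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return np.clip(aff, 0.0, 1.0)


def diffusion_embed(
    affinity: np.ndarray,
    n_components: int = 10,
    alpha: float = 0.5,
    on_disconnected: str = "warn",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    The affinity is alpha-normalized (``W' = D^-a W D^-a``), converted to a
    Markov transition operator by row normalization, and decomposed through
    the conjugate symmetric matrix.  The trivial constant eigenvector
    (eigenvalue 1) is dropped; the remaining components are ordered by
    eigenvalue and scaled by ``lambda / (1 - lambda)`` (diffusion time 0).
    Component signs are arbitrary and fixed later by alignment.

    Returns ``(components, eigenvalues, variance_explained)`` where
    ``variance_explained[k]`` is the k-th non-trivial eigenvalue as a
    fraction of the full non-trivial spectrum (negative part clipped).
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if not np.allclose(w, w.T, atol=1e-10):
        raise GradientError("affinity must be symmetric")
    if np.any(w < 0):
        raise GradientError("affinity must be non-negative")
    d = w.sum(axis=1)
    if np.any(d == 0):
        raise GradientError("affinity has an isolated node (zero degree)")
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d2 = w_alpha.sum(axis=1)
    # symmetric conjugate of the Markov operator D2^-1 W'
    s = w_alpha / np.outer(np.sqrt(d2), np.sqrt(d2))
    evals, evecs = np.linalg.eigh((s + s.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov operator
    psi = evecs / np.sqrt(d2)[:, None]
    # normalize against the trivial (constant) eigenvector
    psi = psi / np.abs(psi[:, 0]).mean()
    if evals[1] > 1.0 - 1e-10:
        msg = "affinity graph appears disconnected (repeated unit eigenvalue)"
        if on_disconnected == "error":
            raise GradientError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    nontrivial_vals = evals[1:]
    nontrivial_vecs = psi[:, 1:]
    k = min(n_components, nontrivial_vals.size)
    lam = nontrivial_vals[:k]
    if abs(lam[0]) < 1e-12:
        warnings.warn(
            "degenerate embedding: leading non-trivial eigenvalue is ~0",
            DegenerateEmbeddingWarning,
            stacklevel=2,
        )
    scale = np.where(np.abs(1.0 - lam) < 1e-12, 0.0, lam / (1.0 - lam))
    components = nontrivial_vecs[:, :k] * scale
    total = np.clip(nontrivial_vals, 0.0, None).sum()
    var_expl = np.clip(lam, 0.0, None) / total if total > 0 else np.zeros(k)
    return components, lam, var_expl


def procrustes_align(
    individual: np.ndarray, reference: np.ndarray, n_iter: int = 10
) -> np.ndarray:
    """Align an individual embedding to a reference by orthogonal Procrustes
    rotation/reflection (no scaling), iterated ``n_iter`` times against the
    fixed reference."""
    x = np.asarray(individual, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise GradientError(
            f"dimension mismatch: individual {x.shape} vs reference {ref.shape}"
        )
    aligned = x
    for _ in range(max(1, n_iter)):
        rot, _ = orthogonal_procrustes(aligned, ref)
        aligned = aligned @ rot
    return aligned


def embed_connectivity(
    conn: np.ndarray | pd.DataFrame,
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparsify -> normalized angle -> diffusion embedding, in one call."""
    sparse = sparsify_rows(conn, density)
    aff = normalized_angle(sparse)
    return diffusion_embed(aff, n_components=n_components, alpha=alpha)


def align_to_template(components: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Rotate an embedding so its first component best matches a template
    gradient.

    Successive eigenvalues of a diffusion embedding can lie close together,
    in which case the leading eigenvectors are only defined up to a rotation
    within their span.  Anchoring the first component to an external
    template (a published gradient map for real data; the planted loading
    for synthetic cohorts) fixes that rotational ambiguity: the direction
    within the component space with maximal least-squares match to the
    template becomes component 1, completed to a full orthonormal rotation.
    """
    comps = np.asarray(components, dtype=float)
    t = np.asarray(template, dtype=float)
    if t.shape[0] != comps.shape[0]:
        raise GradientError("template length must equal the region count")
    w, *_ = np.linalg.lstsq(comps, t - t.mean(), rcond=None)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise GradientError("template is orthogonal to the embedding space")
    w = w / norm
    q, _ = np.linalg.qr(
        np.column_stack([w, np.eye(len(w))])[:, : len(w)]
    )
    if np.dot(q[:, 0], w) < 0:
        q = -q
    out = comps @ q
    if np.corrcoef(out[:, 0], t)[0, 1] < 0:
        out[:, 0] = -out[:, 0]
    return out


def build_group_reference(
    connectivities: Sequence[np.ndarray | pd.DataFrame],
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
    anchor_regions: Sequence[int] | None = None,
    mode: str = "mean-connectivity",
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-level reference gradients.

    ``mode='mean-connectivity'`` (default) embeds the element-wise mean
    connectivity matrix with identical settings; ``mode='iterative-mean'``
    additionally refines that reference by generalized Procrustes passes
    (align every individual embedding to the running reference, average,
    repeat), which averages out per-subject noise.  When a ``template``
    gradient is given the reference is rotated toward it (see
    :func:`align_to_template`) — the analogue of aligning a study's group
    gradient to the published literature gradient.  Otherwise the G1 sign
    is oriented so the mean over ``anchor_regions`` (a transmodal anchor
    set) is positive.
    """
    if len(connectivities) == 0:
        raise GradientError("need at least one subject")
    mean_conn = np.mean([np.asarray(c, dtype=float) for c in connectivities], axis=0)
    comps, evals, var = embed_connectivity(mean_conn, density, n_components, alpha)
    if mode == "iterative-mean":
        embeds = [
            embed_connectivity(c, density, n_components, alpha)[0]
            for c in connectivities
        ]
        for _ in range(3):
            comps = np.mean(
                [procrustes_align(e, comps, n_iter=1) for e in embeds], axis=0
            )
    elif mode != "mean-connectivity":
        raise GradientError(f"unknown reference mode {mode!r}")
    if template is not None:
        comps = align_to_template(comps, template)
    elif anchor_regions is not None and len(anchor_regions) > 0:
        if comps[list(anchor_regions), 0].mean() < 0:
            comps = comps.copy()
            comps[:, 0] = -comps[:, 0]
    return comps, evals, var


def minmax_normalize(g: np.ndarray) -> np.ndarray:
    """Whole-brain per-subject min-max normalization to [0, 100]."""
    g = np.asarray(g, dtype=float)
    lo, hi = g.min(), g.max()
    if hi == lo:
        raise GradientError("constant gradient: min-max normalization undefined")
    return (g - lo) / (hi - lo) * 100.0


class GradientPipeline(BaseEstimator, TransformerMixin):
    """Subject-level principal-gradient estimator.

    ``fit`` builds the group reference from all subjects' connectivity;
    ``transform`` returns each subject's aligned, 0-100-normalized first
    gradient (subjects x regions DataFrame).

    Parameters
    ----------
    density : float
        Fraction of each connectivity row retained by sparsification.
    n_components : int
        Number of diffusion components estimated (alignment space).
    alpha : float
        Anisotropic diffusion normalization exponent.
    n_align_iter : int
        Procrustes iterations against the group reference.
    anchor_regions : sequence of int, optional
        Region indices whose mean reference G1 is forced positive
        (transmodal anchor set); without it the reference sign is arbitrary.
    template : ndarray, optional
        External template gradient (one value per region); when given, the
        reference embedding is rotated so component 1 matches it (the
        study-to-literature alignment step), which also fixes the sign.
    reference_mode : str
        'mean-connectivity' or 'iterative-mean'.

    Attributes
    ----------
    reference_gradients_ : ndarray (n_regions, n_components)
    reference_eigenvalues_ : ndarray
    reference_variance_explained_ : ndarray
    region_ids_ : list of str
    eigenvalues_ : DataFrame, per-subject embedding eigenvalues
    variance_explained_g1_ : Series, per-subject G1 variance fraction
    """

    def __init__(
        self,
        density: float = 0.10,
        n_components: int = 10,
        alpha: float = 0.5,
        n_align_iter: int = 10,
        anchor_regions: Sequence[int] | None = None,
        template: np.ndarray | None = None,
        reference_mode: str = "mean-connectivity",
    ):
        self.density = density
        self.n_components = n_components
        self.alpha = alpha
        self.n_align_iter = n_align_iter
        self.anchor_regions = anchor_regions
        self.template = template
        self.reference_mode = reference_mode

    @staticmethod
    def _as_connectivities(
        X: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    ) -> tuple[list[str], list[pd.DataFrame]]:
        if isinstance(X, Mapping):
            ids = list(X.keys())
            conns = [compute_connectivity(X[s]) for s in ids]
        else:
            ids = [f"sub{i:04d}" for i in range(len(X))]
            conns = [compute_connectivity(ts) for ts in X]
        return ids, conns

    def fit(self, X, y=None):
        ids, conns = self._as_connectivities(X)
        self.region_ids_ = list(conns[0].columns)
        k = min(self.n_components, len(self.region_ids_) - 2)
        ref, evals, var = build_group_reference(
            conns,
            density=self.density,
            n_components=k,
            alpha=self.alpha,
            anchor_regions=self.anchor_regions,
            mode=self.reference_mode,
            template=self.template,
        )
        self.reference_gradients_ = ref
        self.reference_eigenvalues_ = evals
        self.reference_variance_explained_ = var
        self._fit_connectivities = dict(zip(ids, conns))
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_gradients_")
        ids, conns = self._as_connectivities(X)
        k = self.reference_gradients_.shape[1]
        rows, eig_rows, var_g1 = [], [], []
        for sid, conn in zip(ids, conns):
            if list(conn.columns) != self.region_ids_:
                raise GradientError(
                    f"subject {sid}: region set differs from the fitted reference"
                )
            comps, evals, var = embed_connectivity(
                conn, self.density, k, self.alpha
            )
            aligned = procrustes_align(
                comps, self.reference_gradients_, n_iter=self.n_align_iter
            )
            rows.append(minmax_normalize(aligned[:, 0]))
            eig_rows.append(evals)
            var_g1.append(var[0])
        self.eigenvalues_ = pd.DataFrame(eig_rows, index=ids)
        self.variance_explained_g1_ = pd.Series(var_g1, index=ids, name="var_expl_g1")
        return pd.DataFrame(rows, index=ids, columns=self.region_ids_)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def compute_subject_gradients(
    timeseries: Mapping[str, pd.DataFrame],
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
    n_align_iter: int = 10,
    anchor_regions: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, GradientPipeline]:
    """Functional wrapper: fit a :class:`GradientPipeline` and return the
    (subjects x regions) normalized G1 table plus the fitted estimator."""
    pipe = GradientPipeline(
        density=density,
        n_components=n_components,
        alpha=alpha,
        n_align_iter=n_align_iter,
        anchor_regions=anchor_regions,
    )
    g1 = pipe.fit_transform(timeseries)
    return g1, pipe
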