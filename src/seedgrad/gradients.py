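"""Connectivity gradients: normalized-angle affinity and diffusion-map embedding.

The embedding follows the standard diffusion-map construction: density
normalization of the affinity with exponent ``alpha``, row normalization into
a Markov transition operator, and eigendecomposition of its symmetric
conjugate.  Components are ordered by eigenvalue; the trivial constant
component is dropped.  ``DiffusionGradients`` wraps the whole chain as a
scikit-learn style estimator so it composes with sklearn tooling; the
module-level functions are thin wrappers over the same code paths.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ConnectivityMatrix, DegenerateInputError, GradientSet

__all__ = [
    "affinity_matrix",
    "diffusion_embedding",
    "select_components",
    "DiffusionGradients",
]


def affinity_matrix(
    conn: Union[ConnectivityMatrix, np.ndarray], sparsity: float = 0.9
) -> np.ndarray:
    """Normalized-angle affinity between seed-voxel connectivity profiles.

    Each row is sparsified to its top ``1 - sparsity`` fraction of entries
    (the rest set to zero), then the cosine similarity ``c`` between rows is
    mapped to ``1 - arccos(c) / pi``, yielding a symmetric affinity in [0, 1]
    with unit diagonal.

    Raises
    ------
    DegenerateInputError if any row is all-zero after sparsification.
    """
    x = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    x = x.copy()
    if sparsity > 0:
        thresh = np.quantile(x, sparsity, axis=1, keepdims=True)
        x[x < thresh] = 0.0
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DegenerateInputError(
            f"voxel rows {bad.tolist()} are all-zero after sparsification"
        )
    cos = (x / norms[:, None]) @ (x / norms[:, None]).T
    np.clip(cos, -1.0, 1.0, out=cos)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = 0.5 * (aff + aff.T)
    np.fill_diagonal(aff, 1.0)
    return aff


def _diffusion_map(
    affinity: np.ndarray, n_components: int, alpha: float, diffusion_time: float
):
    """Dense diffusion-map eigendecomposition.

    Returns (scores, eigenvalues, explained_variance) for the leading
    ``n_components`` nontrivial components.  ``diffusion_time = 0`` selects
    the automatic multiscale weighting ``lambda / (1 - lambda)``.
    """
    w = np.asarray(affinity, dtype=float)
    m = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if (w < -1e-12).any():
        raise ValueError("affinity must be nonnegative")
    if n_components >= m:
        raise ValueError("n_components must be smaller than the matrix size")

    n_comp_graph, comp_labels = connected_components(w > 0, directed=False)
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} connected components; "
            "embedding components mix disconnected blocks",
            RuntimeWarning,
        )

    d = w.sum(axis=1)
    if (d <= 0).any():
        raise DegenerateInputError("affinity has an isolated all-zero row")
    # density normalization with exponent alpha
    w_a = w / np.outer(d**alpha, d**alpha)
    d_a = w_a.sum(axis=1)
    # symmetric conjugate of the row-normalized transition operator
    inv_sqrt = 1.0 / np.sqrt(d_a)
    s = w_a * np.outer(inv_sqrt, inv_sqrt)
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # eigenvectors of the transition operator; normalize against the trivial
    # stationary component so scores are comparable across voxels
    psi = evecs * inv_sqrt[:, None]
    # normalize against the trivial stationary component; guard the (already
    # warned) disconnected case where it can have near-zero entries
    psi0 = psi[:, [0]]
    safe = np.where(np.abs(psi0) > 1e-12, psi0, 1.0)
    psi = psi / safe
    lam = evals[1 : n_components + 1]
    vecs = psi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1 - 1e-12))
    else:
        scale = lam**diffusion_time
    scores = vecs * scale
    nontrivial = evals[1:]
    pos_sum = nontrivial[nontrivial > 0].sum()
    explained = np.clip(lam, 0, None) / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    return scores, lam, explained, comp_labels


def _orient_signs(scores: np.ndarray, reference: Optional[np.ndarray]) -> np.ndarray:
    """Fix the arbitrary eigenvector signs deterministically.

    With a per-voxel ``reference`` (the first spatial coordinate of the seed
    voxels, by convention) each component is flipped so its correlation with
    the reference is nonnegative; components uncorrelated with the reference,
    or all components when no reference is given, are oriented so the entry
    of largest magnitude is positive.
    """
    out = scores.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        flip = False
        if reference is not None and np.std(col) > 0 and np.std(reference) > 0:
            c = np.corrcoef(col, reference)[0, 1]
            if abs(c) > 1e-12:
                flip = c < 0
            else:
                flip = col[np.argmax(np.abs(col))] < 0
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            out[:, k] = -col
    return out


class DiffusionGradients(TransformerMixin, BaseEstimator):
    """Diffusion-map embedding of a seed-to-cortex connectivity matrix.

    A scikit-learn style estimator: ``fit(X)`` takes an (m, n) connectivity
    matrix (or :class:`ConnectivityMatrix`), builds the normalized-angle
    affinity between seed-voxel rows and embeds it.  Fitted attributes carry
    the per-voxel component scores and the explained-variance fractions that
    weight the detethering formula downstream.

    Parameters
    ----------
    n_components : number of nontrivial components to retain.
    sparsity : per-row sparsification fraction before the cosine (default 0.9,
        i.e. keep the top 10% of each connectivity profile).
    alpha : density-normalization exponent (0.5 = Fokker-Planck convention).
    diffusion_time : 0 selects automatic multiscale scaling.
    random_state : accepted for API compatibility; the dense eigendecomposition
        is deterministic.

    Attributes
    ----------
    gradients_ : (m, K) component scores.
    lambdas_ : (K,) eigenvalues.
    explained_variance_ratio_ : (K,) eigenvalue fractions of the nontrivial
        spectrum.
    affinity_ : (m, m) affinity used.
    """

    def __init__(
        self,
        n_components: int = 10,
        sparsity: float = 0.9,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.sparsity = sparsity
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.random_state = random_state

    def fit(self, X, y=None, orient_reference: Optional[np.ndarray] = None):
        conn = X
        if isinstance(X, ConnectivityMatrix):
            x = X.values
            self._modality = X.modality
            if orient_reference is None and X.seed_region is not None:
                orient_reference = X.seed_region.coords_mm[:, 0]
        else:
            x = np.asarray(X, dtype=float)
            self._modality = ""
        aff = affinity_matrix(x, sparsity=self.sparsity)
        n_comp = min(self.n_components, aff.shape[0] - 1)
        scores, lam, explained, comp_labels = _diffusion_map(
            aff, n_comp, self.alpha, self.diffusion_time
        )
        self.gradients_ = _orient_signs(scores, orient_reference)
        self.lambdas_ = lam
        self.explained_variance_ratio_ = explained
        self.affinity_ = aff
        self.component_graph_labels_ = comp_labels
        return self

    def transform(self, X=None):
        """Return the fitted gradient scores (out-of-sample mapping is not
        defined for a single-dataset embedding)."""
        return self.gradients_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).gradients_

    def to_gradient_set(self, modality: Optional[str] = None) -> GradientSet:
        return GradientSet(
            scores=self.gradients_,
            explained_variance=self.explained_variance_ratio_,
            kernel_params={"kernel": "normalized_angle", "sparsity": self.sparsity},
            embedding_params={
                "alpha": self.alpha,
                "diffusion_time": self.diffusion_time,
            },
            modality=modality if modality is not None else self._modality,
        )


def diffusion_embedding(
    affinity: np.ndarray,
    n_components: int,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    seed: Optional[int] = None,
    orient_reference: Optional[np.ndarray] = None,
) -> GradientSet:
    """Embed a precomputed symmetric affinity matrix.

    Functional wrapper over the same decomposition as
    :class:`DiffusionGradients`; ``seed`` is accepted for interface symmetry
    (the dense decomposition is deterministic).
    """
    scores, lam, explained, _ = _diffusion_map(affinity, n_components, alpha, diffusion_time)
    scores = _orient_signs(scores, orient_reference)
    return GradientSet(
        scores=scores,
        explained_variance=explained,
        kernel_params={"kernel": "precomputed"},
        embedding_params={"alpha": alpha, "diffusion_time": diffusion_time},
    )


def select_components(
    explained_variance: np.ndarray,
    factor: float = 2.0,
    min_components: int = 1,
) -> int:
    """Number of leading components above the variance plateau.

    The default rule retains the largest ``k`` such that every component up to
    ``k`` exceeds ``factor`` times the median of the trailing spectrum beyond
    it.  A flat spectrum retains ``min_components``.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.size < 3:
        raise ValueError("need at least 3 components to locate a plateau")
    k = 0
    for i in range(ev.size - 1):
        tail = ev[i + 1 :]
        if ev[i] > factor * np.median(tail):
            k = i + 1
        else:
            break
    return max(k, min_components)
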