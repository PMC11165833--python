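"""Diffusion-map gradients of connectivity matrices and Procrustes alignment.

The embedding follows the standard connectome-gradient recipe: row-wise
sparsification of the connectivity profile, a normalized-angle similarity
kernel, then diffusion map embedding of the alpha-normalized random-walk
operator (alpha = 0.5, i.e. Fokker-Planck normalization). Individual
embeddings are aligned to a template by orthogonal Procrustes rotation
(reflections allowed, no scaling — scaling would absorb the radial
expansion/contraction signal that manifold eccentricity quantifies).

Eigenvector signs are fixed deterministically (the entry of largest absolute
value is made positive) because the sign of an eigenvector is arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


def affinity(matrix: np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Normalized-angle affinity between row-thresholded connectivity profiles.

    Per row, entries below that row's ``sparsity`` quantile are zeroed; the
    similarity between two rows is ``1 - (2/pi) * arccos(cosine similarity)``,
    clipped to [0, 1], with unit diagonal.
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity requires a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity requires a symmetric matrix")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    if sparsity > 0:
        cut = np.quantile(w, sparsity, axis=1, keepdims=True)
        w = np.where(w >= cut, w, 0.0)
    norms = np.linalg.norm(w, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValueError(f"regions {dead.tolist()} have empty connectivity profiles after thresholding")
    cos = (w @ w.T) / np.outer(norms, norms)
    np.clip(cos, -1.0, 1.0, out=cos)
    ang = 1.0 - (2.0 / np.pi) * np.arccos(cos)
    np.clip(ang, 0.0, 1.0, out=ang)
    ang = (ang + ang.T) / 2.0
    np.fill_diagonal(ang, 1.0)
    return ang


@dataclass
class DiffusionResult:
    components: np.ndarray  # (n, K) diffusion coordinates
    eigenvalues: np.ndarray  # (K,) nontrivial eigenvalues, non-increasing
    all_eigenvalues: np.ndarray  # full nontrivial spectrum (descending)
    variance_explained: np.ndarray  # (K,) lambda_k / sum of positive nontrivial lambdas


def diffusion_map(
    affinity_matrix: np.ndarray,
    n_components: int = 3,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> DiffusionResult:
    """Diffusion map embedding of a symmetric non-negative affinity matrix.

    With degrees ``d_i``, the kernel is re-normalized as
    ``W'_ij = W_ij / (d_i^alpha d_j^alpha)`` and the random-walk operator
    ``P = D'^-1 W'`` is eigendecomposed through its symmetric conjugate. The
    stationary eigenvector (eigenvalue 1) is dropped; with the automatic
    diffusion-time rule (``diffusion_time = 0``) component k is
    ``psi_k * lambda_k / (1 - lambda_k)``, otherwise ``psi_k * lambda_k**t``.
    """
    w = np.asarray(affinity_matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if (w < 0).any():
        raise ValueError("affinity must be non-negative")
    n = w.shape[0]
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n")

    d = w.sum(1)
    if (d <= 0).any():
        raise ValueError("affinity has zero-degree rows")
    w1 = w / np.outer(d**alpha, d**alpha)
    q = w1.sum(1)
    # symmetric conjugate of the row-normalized operator: same spectrum
    s = w1 / np.sqrt(np.outer(q, q))
    evals, evecs = scipy.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(q)[:, None]  # right eigenvectors of P
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)

    lam = evals[1:]  # drop stationary lambda_0 = 1
    psi = psi[:, 1:]
    if lam.size and lam[0] >= 1.0 - 1e-10:
        raise ValueError(
            "affinity graph is disconnected (repeated unit eigenvalue); "
            "lower the kernel sparsity or densify the input matrix"
        )
    k = n_components
    lam_k = lam[:k]
    if diffusion_time == 0:
        scale = lam_k / (1.0 - lam_k)
    else:
        scale = lam_k**diffusion_time
    comps = psi[:, :k] * scale
    # deterministic sign: largest-|value| entry positive per component
    for j in range(comps.shape[1]):
        imax = int(np.argmax(np.abs(comps[:, j])))
        if comps[imax, j] < 0:
            comps[:, j] = -comps[:, j]
    pos = lam[lam > 0]
    denom = pos.sum() if pos.size else 1.0
    var = np.clip(lam[:k], 0.0, None) / denom
    return DiffusionResult(
        components=comps,
        eigenvalues=lam[:k],
        all_eigenvalues=lam,
        variance_explained=var,
    )


def procrustes_align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate/reflect ``source`` onto ``target`` (no scaling, no centering)."""
    r, _ = scipy.linalg.orthogonal_procrustes(source, target)
    return source @ r


@dataclass
class GradientSet:
    """Template gradients plus optionally Procrustes-aligned subject gradients."""

    template: np.ndarray  # (n_regions, K)
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    all_eigenvalues: np.ndarray
    params: dict = field(default_factory=dict)
    aligned: Optional[np.ndarray] = None  # (n_subjects, n_regions, K)
    subject_ids: Optional[list] = None
    excluded_subjects: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.template.shape[1]


class GradientEmbedding(BaseEstimator, TransformerMixin):
    """Template diffusion-map gradients with per-subject Procrustes alignment.

    ``fit(X)`` takes a group-representative connectivity matrix and stores
    ``template_``, ``eigenvalues_`` and ``variance_explained_``;
    ``transform(X)`` embeds one matrix or a (subjects, n, n) stack with the
    same parameters and aligns each embedding to the template.

    Parameters
    ----------
    n_components : number of gradients K (default 3).
    sparsity : row-wise threshold quantile of the affinity kernel (default 0.9).
    alpha : diffusion-operator normalization exponent (default 0.5).
    diffusion_time : 0 selects the automatic lambda/(1-lambda) scaling.
    """

    def __init__(self, n_components: int = 3, sparsity: float = 0.9, alpha: float = 0.5, diffusion_time: float = 0.0):
        self.n_components = n_components
        self.sparsity = sparsity
        self.alpha = alpha
        self.diffusion_time = diffusion_time

    def _embed(self, matrix: np.ndarray) -> DiffusionResult:
        return diffusion_map(
            affinity(matrix, sparsity=self.sparsity),
            n_components=self.n_components,
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
        )

    def fit(self, X, y=None):
        res = self._embed(np.asarray(X, dtype=float))
        self.template_ = res.components
        self.eigenvalues_ = res.eigenvalues
        self.variance_explained_ = res.variance_explained
        self.all_eigenvalues_ = res.all_eigenvalues
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "template_"):
            raise RuntimeError("GradientEmbedding must be fitted before transform")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        stack = X[None] if single else X
        out = np.empty((stack.shape[0], self.template_.shape[0], self.n_components))
        for s in range(stack.shape[0]):
            res = self._embed(stack[s])
            out[s] = procrustes_align(res.components, self.template_)
        return out[0] if single else out

    def gradient_set(self) -> GradientSet:
        return GradientSet(
            template=self.template_,
            eigenvalues=self.eigenvalues_,
            variance_explained=self.variance_explained_,
            all_eigenvalues=self.all_eigenvalues_,
            params=self.get_params(),
        )


def template_gradients(consensus_matrix: np.ndarray, n_components: int = 3, sparsity: float = 0.9, alpha: float = 0.5) -> GradientSet:
    """Template gradients of a group-representative matrix."""
    est = GradientEmbedding(n_components=n_components, sparsity=sparsity, alpha=alpha)
    return est.fit(consensus_matrix).gradient_set()


def embed_individuals(cohort, template: GradientSet) -> GradientSet:
    """Embed every subject's cortical connectome and align it to the template.

    Subjects whose kernel fails (e.g. an empty connectivity profile after
    thresholding) are excluded with a logged reason rather than aborting the
    cohort.
    """
    est = GradientEmbedding(**template.params) if template.params else GradientEmbedding()
    est.template_ = template.template
    est.eigenvalues_ = template.eigenvalues
    est.variance_explained_ = template.variance_explained
    est.all_eigenvalues_ = template.all_eigenvalues

    mats = cohort.cortical_matrices()
    aligned, kept_ids, excluded = [], [], []
    for s in range(mats.shape[0]):
        sid = cohort.subjects["subject_id"].iloc[s]
        try:
            aligned.append(est.transform(mats[s]))
            kept_ids.append(sid)
        except ValueError as exc:
            logger.warning("excluding subject %s from embedding: %s", sid, exc)
            excluded.append(sid)
    if not aligned:
        raise ValueError("no subject could be embedded")
    return GradientSet(
        template=template.template,
        eigenvalues=template.eigenvalues,
        variance_explained=template.variance_explained,
        all_eigenvalues=template.all_eigenvalues,
        params=template.params,
        aligned=np.array(aligned),
        subject_ids=kept_ids,
        excluded_subjects=excluded,
    )
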