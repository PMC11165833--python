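"""Manifold eccentricity: radial position of each region in gradient space.

Eccentricity collapses K aligned gradients into one interpretable per-region
scalar — the Euclidean distance between a region's position in the manifold
and the center of the point cloud. Regions that move away from the center
between groups have "expanded" in connectome space; regions that move toward
it have "contracted".

The center defaults to the centroid of the *template* manifold, so every
subject is measured against a common reference; a subject-wise centroid is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .gradients import GradientSet


@dataclass
class EccentricityMatrix:
    values: np.ndarray  # (n_subjects, n_regions), >= 0
    n_components: int
    center_rule: str
    center: np.ndarray  # (K,) template centroid, or (n_subjects, K) per-subject
    subject_ids: list = None


class ManifoldEccentricity(BaseEstimator, TransformerMixin):
    """Transformer from aligned gradients to per-region eccentricity.

    ``fit(X)`` takes the template gradient matrix (regions x K) and stores the
    manifold center; ``transform(X)`` maps aligned subject gradients — one
    (regions x K) matrix or a (subjects, regions, K) stack — to eccentricity
    values over the first ``n_components`` gradients.

    Parameters
    ----------
    n_components : number of gradients used (None = all available).
    center : 'template' (common template centroid, default) or 'subject'
        (each subject's own manifold centroid).
    """

    def __init__(self, n_components: int = None, center: str = "template"):
        self.n_components = n_components
        self.center = center

    def _k(self, available: int) -> int:
        k = available if self.n_components is None else int(self.n_components)
        if not 1 <= k <= available:
            raise ValueError(f"n_components={k} outside available 1..{available}")
        return k

    def fit(self, X, y=None):
        template = np.asarray(X, dtype=float)
        k = self._k(template.shape[1])
        self.center_ = template[:, :k].mean(axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        stack = X[None] if single else X
        k = self._k(stack.shape[2])
        g = stack[:, :, :k]
        if self.center == "template":
            if not hasattr(self, "center_"):
                raise RuntimeError("fit on the template before transform with center='template'")
            center = self.center_[None, None, :]
        elif self.center == "subject":
            center = g.mean(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown center rule {self.center!r}")
        ecc = np.sqrt(((g - center) ** 2).sum(axis=2))
        return ecc[0] if single else ecc


def manifold_eccentricity(gradients: GradientSet, n_components: int = None, center: str = "template") -> EccentricityMatrix:
    """Eccentricity of every subject's aligned gradients."""
    if gradients.aligned is None:
        raise ValueError("GradientSet has no aligned subject gradients")
    est = ManifoldEccentricity(n_components=n_components, center=center)
    est.fit(gradients.template)
    values = est.transform(gradients.aligned)
    k = est._k(gradients.aligned.shape[2])
    if center == "template":
        used_center = est.center_
    else:
        used_center = gradients.aligned[:, :, :k].mean(axis=1)
    return EccentricityMatrix(
        values=values,
        n_components=k,
        center_rule=center,
        center=used_center,
        subject_ids=gradients.subject_ids,
    )
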