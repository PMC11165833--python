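"""Permutation-based group contrasts with covariate adjustment and BH-FDR.

The effect measure per region is the t-statistic of the group term in an
ordinary least-squares model

    feature ~ intercept + group (patient = 1) + age + sex,

i.e. a covariance-adjusted group contrast (for a single contrast F = t^2, so
this is the ANCOVA group effect). Significance is non-parametric: group
labels are permuted over subjects (covariates stay attached to their
subjects), the t-map is recomputed for every permutation — one shared
permutation per draw across all regions, preserving their spatial
correlation — and the empirical p-value is the fraction of permuted |t|
exceeding the observed |t|. By that counting rule p = 0 is attainable; the
(b+1)/(m+1) correction is available but off by default. Region-wise q-values
come from Benjamini-Hochberg step-up correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas, NETWORKS7, HIERARCHY4


def _design_matrix(group01: np.ndarray, covariates: np.ndarray = None) -> np.ndarray:
    n = len(group01)
    cols = [np.ones(n), np.asarray(group01, dtype=float)]
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, dtype=float).T)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (e.g. a constant covariate such as a "
            "single-sex cohort); remove the offending covariate"
        )
    return x


def _group_t(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """t of the group coefficient (column 1) for every feature column of y.

    Zero residual variance or zero numerator yields t = 0 (degenerate case).
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    # a numerically zero SE marks a degenerate (e.g. constant) feature -> t = 0
    floor = 1e-10 * (1.0 + np.abs(y).max(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > floor, beta[1] / np.where(se > floor, se, 1.0), 0.0)
    return t


def encode_group(group) -> np.ndarray:
    """patient -> 1, control -> 0."""
    g = np.asarray(group)
    if g.dtype.kind in "OUS":
        return (g == "patient").astype(float)
    return g.astype(float)


def encode_covariates(age=None, sex=None) -> np.ndarray:
    """Stack age and a 0/1 sex indicator (F = 1) into a covariate matrix."""
    cols = []
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
    if sex is not None:
        s = np.asarray(sex)
        cols.append((s == "F").astype(float) if s.dtype.kind in "OUS" else s.astype(float))
    if not cols:
        return np.empty((0, 0))
    return np.column_stack(cols)


def ancova_t(feature, group, age=None, sex=None) -> float:
    """Covariate-adjusted group-contrast t for a single feature.

    With no covariates this is the classical pooled-variance two-sample t
    (patients minus controls).
    """
    y = np.asarray(feature, dtype=float)[:, None]
    cov = encode_covariates(age, sex)
    x = _design_matrix(encode_group(group), cov if cov.size else None)
    return float(_group_t(y, x)[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PermutationResult:
    """Region-wise permutation contrast with FDR correction."""

    region_ids: np.ndarray
    t_obs: np.ndarray  # patients minus controls
    p_perm: np.ndarray
    q_fdr: np.ndarray
    significant: np.ndarray
    direction: np.ndarray  # expansion/contraction or increase/decrease or none
    n_permutations: int
    seed: int = None
    covariates: tuple = ()
    fdr_alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids,
                "statistic": self.t_obs,
                "p_value": self.p_perm,
                "q_value": self.q_fdr,
                "significant": self.significant,
                "direction": self.direction,
            }
        )


class PermutationGroupContrast(BaseEstimator):
    """Permutation ANCOVA over a subjects x regions feature matrix.

    ``fit(X, y)`` takes features and group labels (strings or 0/1) with
    optional ``covariates`` (subjects x c) and computes ``t_obs_``, ``p_``,
    ``q_`` and ``significant_``.

    Parameters
    ----------
    n_permutations : label permutations used for the null (study default 10000).
    fdr_alpha : FDR significance threshold (default 0.05).
    random_state : permutation seed.
    add_one_correction : use (b+1)/(m+1) instead of the plain b/m counting.
    direction_labels : pair used to label positive/negative contrasts.
    """

    def __init__(
        self,
        n_permutations: int = 10000,
        fdr_alpha: float = 0.05,
        random_state: int = 0,
        add_one_correction: bool = False,
        direction_labels: tuple = ("expansion", "contraction"),
    ):
        self.n_permutations = n_permutations
        self.fdr_alpha = fdr_alpha
        self.random_state = random_state
        self.add_one_correction = add_one_correction
        self.direction_labels = direction_labels

    def fit(self, X, y, covariates: np.ndarray = None, permutations: np.ndarray = None):
        feats = np.asarray(X, dtype=float)
        if feats.ndim == 1:
            feats = feats[:, None]
        g = encode_group(y)
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.size == 0:
                cov = None
        n = feats.shape[0]
        if len(g) != n:
            raise ValueError("feature rows and group labels disagree")
        if min((g == 1).sum(), (g == 0).sum()) < 2:
            raise ValueError("need at least 2 subjects per group")

        x_obs = _design_matrix(g, cov)
        t_obs = _group_t(feats, x_obs)

        if permutations is None:
            rng = np.random.default_rng(self.random_state)
            n_perm = int(self.n_permutations)
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        else:
            perms = np.asarray(permutations, dtype=int)
            n_perm = perms.shape[0]
        if n_perm < 1:
            raise ValueError("need at least one permutation")

        exceed = np.zeros(feats.shape[1], dtype=int)
        abs_obs = np.abs(t_obs)
        for b in range(n_perm):
            x_b = _design_matrix(g[perms[b]], cov)
            t_b = _group_t(feats, x_b)
            exceed += np.abs(t_b) > abs_obs
        if self.add_one_correction:
            p = (exceed + 1) / (n_perm + 1)
        else:
            p = exceed / n_perm
        q = bh_fdr(p)

        self.t_obs_ = t_obs
        self.p_ = p
        self.q_ = q
        self.significant_ = q < self.fdr_alpha
        pos, neg = self.direction_labels
        self.direction_ = np.where(t_obs > 0, pos, np.where(t_obs < 0, neg, "none"))
        self.n_permutations_ = n_perm
        return self

    def result(self, region_ids=None) -> PermutationResult:
        if region_ids is None:
            region_ids = np.arange(len(self.t_obs_))
        return PermutationResult(
            region_ids=np.asarray(region_ids),
            t_obs=self.t_obs_,
            p_perm=self.p_,
            q_fdr=self.q_,
            significant=self.significant_,
            direction=self.direction_,
            n_permutations=self.n_permutations_,
            seed=self.random_state,
            covariates=("age", "sex"),
            fdr_alpha=self.fdr_alpha,
        )


def permutation_test(
    features: np.ndarray,
    group,
    covariates: np.ndarray = None,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    region_ids=None,
    permutations: np.ndarray = None,
    direction_labels: tuple = ("expansion", "contraction"),
) -> PermutationResult:
    """Functional wrapper over :class:`PermutationGroupContrast`."""
    est = PermutationGroupContrast(
        n_permutations=n_perm,
        fdr_alpha=fdr_alpha,
        random_state=seed,
        direction_labels=direction_labels,
    )
    est.fit(features, group, covariates=covariates, permutations=permutations)
    return est.result(region_ids)


@dataclass
class NetworkSummary:
    """Mean contrast statistic per partition class."""

    partition: str
    class_means: dict = field(default_factory=dict)

    def max_class(self) -> str:
        finite = {k: v for k, v in self.class_means.items() if v == v}
        return max(finite, key=finite.get)


def stratify(result: PermutationResult, atlas: RegionAtlas, partition: str = "network7") -> NetworkSummary:
    """Summarize region-wise t-statistics by network or hierarchy class."""
    if partition == "network7":
        labels, classes = atlas.network_labels(), NETWORKS7
    elif partition == "hierarchy4":
        labels, classes = atlas.hierarchy_labels(), HIERARCHY4
    else:
        raise ValueError(f"unknown partition {partition!r}")
    t = pd.Series(result.t_obs, index=result.region_ids)
    means = {}
    for c in classes:
        ids = labels.index[labels == c]
        ids = ids.intersection(t.index)
        means[c] = float(t.loc[ids].mean()) if len(ids) else float("nan")
    return NetworkSummary(partition=partition, class_means=means)
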