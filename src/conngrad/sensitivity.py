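"""Sensitivity variants: rerun the contrast under modified conditions.

Each variant filters the subject table (e.g. drop patients with aura, keep a
single headache phase, exclude depression/anxiety), overrides the gradient
count, or drops the covariates, then reruns the full contrast pipeline and
compares the resulting region-wise t-map with the reference map by Pearson
correlation. When only the subject set changes the reference template is
reused as the alignment target, isolating the subject effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .gradients import GradientSet
from .pipeline import contrast_pipeline
from .simulate import ConnectomeCohort
from .stats import PermutationResult


@dataclass
class VariantSpec:
    """One sensitivity configuration.

    ``subject_filter`` options: ``exclude_aura``, ``phase:<name>``,
    ``exclude_depression_anxiety``, ``low_frequency`` (alias for excluding
    flagged subjects). ``n_components`` overrides the gradient count;
    ``use_covariates=False`` drops age/sex adjustment.
    """

    name: str
    subject_filter: Optional[str] = None
    n_components: Optional[int] = None
    use_covariates: bool = True


@dataclass
class MapComparison:
    name: str
    r: float
    p: float
    n_regions: int
    result: PermutationResult = field(default=None, repr=False)


def _filter_mask(cohort: ConnectomeCohort, rule: Optional[str]) -> np.ndarray:
    subj = cohort.subjects
    keep = np.ones(len(subj), dtype=bool)
    if rule is None:
        return keep
    is_control = (subj["group"] == "control").to_numpy()
    if rule == "exclude_aura":
        keep = is_control | (subj["aura"].to_numpy() != "yes")
    elif rule.startswith("phase:"):
        phase = rule.split(":", 1)[1]
        if phase not in {"interictal", "peri_ictal", "ictal"}:
            raise ValueError(f"unknown phase filter {phase!r}")
        keep = is_control | (subj["phase"].to_numpy() == phase)
    elif rule in ("exclude_depression_anxiety", "low_frequency"):
        flagged = (subj["depression"].to_numpy() > 0) | (subj["anxiety"].to_numpy() > 0)
        keep = is_control | ~flagged
    else:
        raise ValueError(f"unknown subject filter {rule!r}")
    return keep


def map_correlation(t_a: np.ndarray, t_b: np.ndarray) -> tuple:
    """Pearson r between two region-wise t maps and its two-tailed p."""
    r, p = sps.pearsonr(np.asarray(t_a, float), np.asarray(t_b, float))
    return float(r), float(p)


def run_variant(
    cohort: ConnectomeCohort,
    spec: VariantSpec,
    reference: PermutationResult,
    template: Optional[GradientSet] = None,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    **pipeline_kwargs,
) -> MapComparison:
    """Run one sensitivity variant and correlate its t-map with the reference."""
    mask = _filter_mask(cohort, spec.subject_filter)
    sub = cohort.subset(mask)
    groups = sub.subjects["group"]
    for g in ("patient", "control"):
        if (groups == g).sum() < 2:
            raise ValueError(f"filter {spec.subject_filter!r} leaves fewer than 2 {g}s")
    if (
        template is not None
        and spec.n_components is not None
        and spec.n_components != template.n_components
    ):
        template = None  # a different gradient count needs a recomputed template
    out = contrast_pipeline(
        sub,
        n_components=spec.n_components or (template.n_components if template is not None else 3),
        n_perm=n_perm,
        seed=seed,
        fdr_alpha=fdr_alpha,
        use_covariates=spec.use_covariates,
        template=template,
        stratify_results=False,
        **pipeline_kwargs,
    )
    ref = dict(zip(np.asarray(reference.region_ids), reference.t_obs))
    var = dict(zip(np.asarray(out.result.region_ids), out.result.t_obs))
    common = sorted(set(ref) & set(var))
    r, p = map_correlation([ref[i] for i in common], [var[i] for i in common])
    return MapComparison(name=spec.name, r=r, p=p, n_regions=len(common), result=out.result)


def eigenvector_count_for_variance(eigenvalues, target_fraction: float) -> int:
    """Smallest K whose cumulative variance fraction reaches the target.

    Eigenvalues must be descending and positive; they are normalized to
    fractions internally. A target above the total explained returns the full
    count.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues given")
    if (np.diff(lam) > 1e-12).any():
        raise ValueError("eigenvalues must be in descending order")
    if (lam <= 0).any():
        raise ValueError("eigenvalues must be positive")
    frac = np.cumsum(lam) / lam.sum()
    hit = np.flatnonzero(frac >= target_fraction - 1e-12)
    if hit.size == 0:
        import warnings

        warnings.warn(f"target fraction {target_fraction} exceeds total explained; returning all {lam.size}")
        return int(lam.size)
    return int(hit[0] + 1)
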