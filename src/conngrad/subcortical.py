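"""Subcortico-cortical degree analysis.

The cortical gradient analysis leaves the subcortex untouched; here each
subcortical structure is summarized by its degree — the sum of edge weights
connecting it to all cortical regions (cortico-cortical and
subcortico-subcortical edges are excluded). Group contrasts reuse the same
permutation-ANCOVA machinery as the cortical analysis, with FDR correction
across the subcortical structures only. Left and right structures are tested
separately by default; hemisphere averaging is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ConnectomeCohort
from .stats import PermutationResult, permutation_test


@dataclass
class SubcorticalDegree:
    values: np.ndarray  # (n_subjects, n_subcortical)
    region_ids: np.ndarray
    names: list  # e.g. lh_caudate
    structures: list  # bare structure names (caudate, ...)
    subject_ids: list = None


def subcortical_degree(cohort: ConnectomeCohort, average_hemispheres: bool = False) -> SubcorticalDegree:
    """Per-subject degree of every subcortical structure to the cortex."""
    sub_ids = cohort.atlas.subcortical_ids
    if sub_ids.size == 0:
        raise ValueError("atlas has no subcortical regions")
    cort_ids = cohort.atlas.cortical_ids
    vals = cohort.matrices[:, sub_ids[:, None], cort_ids[None, :]].sum(axis=2)
    names = cohort.atlas.table.loc[sub_ids, "name"].tolist()
    structures = cohort.atlas.table.loc[sub_ids, "subcortical_name"].tolist()
    if average_hemispheres:
        uniq = list(dict.fromkeys(structures))
        out = np.zeros((vals.shape[0], len(uniq)))
        for k, s in enumerate(uniq):
            cols = [i for i, name in enumerate(structures) if name == s]
            out[:, k] = vals[:, cols].mean(axis=1)
        return SubcorticalDegree(
            values=out,
            region_ids=np.arange(len(uniq)),
            names=uniq,
            structures=uniq,
            subject_ids=cohort.subjects["subject_id"].tolist(),
        )
    return SubcorticalDegree(
        values=vals,
        region_ids=sub_ids,
        names=names,
        structures=structures,
        subject_ids=cohort.subjects["subject_id"].tolist(),
    )


def subcortical_contrast(
    degree: SubcorticalDegree,
    group,
    covariates: np.ndarray = None,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> PermutationResult:
    """Permutation group contrast on degree values, FDR across structures."""
    return permutation_test(
        degree.values,
        group,
        covariates=covariates,
        n_perm=n_perm,
        seed=seed,
        fdr_alpha=fdr_alpha,
        region_ids=degree.region_ids,
        direction_labels=("increase", "decrease"),
    )


def degree_frame(degree: SubcorticalDegree) -> pd.DataFrame:
    return pd.DataFrame(degree.values, columns=degree.names, index=degree.subject_ids)
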