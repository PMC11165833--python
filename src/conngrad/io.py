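"""Text-based cohort and result-table I/O.

Interchange formats are deliberately plain: TSV for tables, dense
whitespace-delimited text for connectivity matrices, JSON for the simulation
truth record. Region indices are 0-based everywhere and subject order is
defined by the row order of ``subjects.tsv``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, _ATLAS_COLUMNS
from .simulate import ConnectomeCohort

logger = logging.getLogger(__name__)

VALID_GROUPS = {"patient", "control"}

RESULT_COLUMNS = ["region", "statistic", "p_value", "q_value", "significant", "direction"]


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g")


def read_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if np.isnan(m).any():
        ij = np.argwhere(np.isnan(m))
        raise ValueError(f"matrix {path} contains NaN at entries {ij[:5].tolist()}")
    return m


def write_cohort(cohort: ConnectomeCohort, path) -> Path:
    """Write a cohort directory: atlas.tsv, subjects.tsv, truth.json, matrices/."""
    path = Path(path)
    (path / "matrices").mkdir(parents=True, exist_ok=True)
    cohort.atlas.table.to_csv(path / "atlas.tsv", sep="\t", index=False)
    cohort.subjects.to_csv(path / "subjects.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        (path / "truth.json").write_text(json.dumps(cohort.truth, indent=1))
    for sid, mat in zip(cohort.subjects["subject_id"], cohort.matrices):
        write_matrix(mat, path / "matrices" / f"{sid}.txt")
    return path


def read_cohort(path, symmetry_tol: float = 1e-8) -> ConnectomeCohort:
    """Read and validate a cohort directory written by :func:`write_cohort`.

    Matrices asymmetric beyond ``symmetry_tol`` are symmetrized as
    ``(A + A.T) / 2`` with a warning; NaNs and negative weights are errors.
    """
    path = Path(path)
    atlas = RegionAtlas(pd.read_csv(path / "atlas.tsv", sep="\t", keep_default_na=False)[_ATLAS_COLUMNS])
    subjects = pd.read_csv(path / "subjects.tsv", sep="\t")
    bad = ~subjects["group"].isin(VALID_GROUPS)
    if bad.any():
        rows = subjects.index[bad].tolist()
        raise ValueError(
            f"subjects.tsv rows {rows} have unknown group labels "
            f"{subjects.loc[bad, 'group'].unique().tolist()}; expected {sorted(VALID_GROUPS)}"
        )
    missing = [
        sid for sid in subjects["subject_id"] if not (path / "matrices" / f"{sid}.txt").exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing matrix files for subjects: {missing}")

    mats = []
    for sid in subjects["subject_id"]:
        m = read_matrix(path / "matrices" / f"{sid}.txt")
        if m.shape != (atlas.n_regions, atlas.n_regions):
            raise ValueError(f"{sid}: matrix shape {m.shape} does not match atlas size {atlas.n_regions}")
        if (m < 0).any():
            raise ValueError(f"{sid}: negative weights present")
        asym = np.abs(m - m.T).max()
        if asym > symmetry_tol:
            warnings.warn(f"{sid}: asymmetry up to {asym:.3g}; symmetrizing as (A + A.T)/2")
            logger.warning("%s: symmetrized input matrix (max asymmetry %.3g)", sid, asym)
            m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        mats.append(m)

    truth = None
    if (path / "truth.json").exists():
        truth = json.loads((path / "truth.json").read_text())
    return ConnectomeCohort(atlas=atlas, matrices=np.array(mats), subjects=subjects, truth=truth)


def result_table(region, statistic, p_value, q_value, significant, direction) -> pd.DataFrame:
    """Assemble a canonical result table sorted by region key."""
    df = pd.DataFrame(
        {
            "region": region,
            "statistic": statistic,
            "p_value": p_value,
            "q_value": q_value,
            "significant": np.asarray(significant, dtype=bool),
            "direction": direction,
        }
    )
    return df.sort_values("region", kind="stable").reset_index(drop=True)


def write_results(table: pd.DataFrame, path) -> Path:
    """Write a result table as TSV with 6-significant-digit floats."""
    path = Path(path)
    out = table[RESULT_COLUMNS].copy()
    for col in ("statistic", "p_value", "q_value"):
        out[col] = out[col].map(lambda v: f"{float(v):.6g}")
    out["significant"] = out["significant"].astype(bool)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if len(df):
        df["significant"] = df["significant"].astype(bool)
    return df[RESULT_COLUMNS] if len(df) else df
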