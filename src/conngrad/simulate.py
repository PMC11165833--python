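"""Synthetic cohort generator with planted group effects.

The generator produces per-subject weighted structural connectomes from a
latent-geometry model: every region carries a low-dimensional latent position
(tied to its mirrored centroid coordinates, so the recovered gradients emulate
left-right / anterior-posterior / third axes), and the expected edge weight
decays exponentially in both latent distance and physical inter-centroid
distance,

    w_ij  ∝  exp(-||g_i - g_j||) * exp(-d_ij / lambda_d).

Group effects are planted directly in the quantities the downstream analysis
measures: patients' limbic-network latent positions are displaced radially
outward by (1 + delta_e) and somatomotor positions inward by (1 - delta_c)
relative to the cortical latent centroid, and patients' caudate / amygdala /
accumbens connections are scaled by a multiplicative degree factor. With all
effects switched off the two groups are exchangeable by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .atlas import RegionAtlas, make_atlas

logger = logging.getLogger(__name__)

EXPANSION_NETWORK = "limbic"
CONTRACTION_NETWORK = "somatomotor"
DEGREE_EFFECT_STRUCTURES = ("caudate", "amygdala", "accumbens")

# Patient covariate frequencies emulating an episodic-migraine clinic cohort
# (phase mix interictal/peri-ictal/ictal, ~15% aura, ~17% depression/anxiety).
_PHASE_PROBS = {"interictal": 26 / 47, "peri_ictal": 6 / 47, "ictal": 15 / 47}
_AURA_PROB = 7 / 47
_DEPRESSION_PROB = 8 / 47
_ANXIETY_PROB = 8 / 47


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the study conditions the pipeline is exercised under:
    100 cortical parcels + 14 subcortical structures, 47 patients vs 41
    controls, a three-dimensional latent geometry, 50% radial limbic
    expansion, 30% somatomotor contraction, a 1.5x subcortical degree factor
    and sigma = 0.2 multiplicative log-normal edge noise.
    """

    n_cortical: int = 100
    n_subcortical: int = 14
    n_patients: int = 47
    n_controls: int = 41
    latent_dim: int = 3
    effect_expand: float = 0.5
    effect_contract: float = 0.3
    subcortical_degree_effect: float = 1.5
    distance_decay: float = 150.0
    edge_noise_sd: float = 0.2
    latent_noise_sd: float = 0.25
    density: float = 0.35
    shell_radius: float = 60.0
    latent_scales: tuple = (1.4, 1.05, 0.8)
    spatial_coupling: float = 0.5
    age_range: tuple = (25.0, 50.0)
    sex_ratio_female: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.effect_expand < 0 or self.effect_contract < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.effect_contract >= 1:
            raise ValueError("effect_contract must be < 1")
        if self.subcortical_degree_effect < 1:
            raise ValueError("subcortical_degree_effect must be >= 1")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.distance_decay <= 0:
            raise ValueError("distance_decay must be > 0")
        if self.edge_noise_sd < 0 or self.latent_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if min(self.n_patients, self.n_controls) < 1:
            raise ValueError("both groups need at least one subject")


@dataclass
class ConnectomeCohort:
    """Stack of per-subject connectomes plus covariates and region metadata."""

    atlas: RegionAtlas
    matrices: np.ndarray  # (n_subjects, n_regions, n_regions)
    subjects: pd.DataFrame
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3:
            raise ValueError("matrices must be a (subjects, regions, regions) stack")
        if self.matrices.shape[0] != len(self.subjects):
            raise ValueError("subjects table row count must equal the number of matrices")
        if self.matrices.shape[1] != self.atlas.n_regions or self.matrices.shape[2] != self.atlas.n_regions:
            raise ValueError("matrix dimension must equal the atlas size")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def group(self) -> np.ndarray:
        return self.subjects["group"].to_numpy()

    @property
    def is_patient(self) -> np.ndarray:
        return self.group == "patient"

    def cortical_matrices(self) -> np.ndarray:
        idx = self.atlas.cortical_ids
        return self.matrices[:, idx[:, None], idx[None, :]]

    def validate(self, atol: float = 1e-8) -> None:
        if np.isnan(self.matrices).any():
            raise ValueError("cohort matrices contain NaN")
        if (self.matrices < 0).any():
            raise ValueError("cohort matrices contain negative weights")
        if not np.allclose(self.matrices, np.swapaxes(self.matrices, 1, 2), atol=atol):
            raise ValueError("cohort matrices are not symmetric")
        diags = self.matrices[:, np.arange(self.matrices.shape[1]), np.arange(self.matrices.shape[1])]
        if not np.allclose(diags, 0.0, atol=atol):
            raise ValueError("cohort matrices must have zero diagonal")

    def subset(self, mask: np.ndarray) -> "ConnectomeCohort":
        mask = np.asarray(mask)
        return ConnectomeCohort(
            atlas=self.atlas,
            matrices=self.matrices[mask],
            subjects=self.subjects.loc[mask].reset_index(drop=True),
            truth=self.truth,
        )


def _latent_positions(atlas: RegionAtlas, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared latent coordinates: a volumetric Gaussian cloud with ordered scales.

    Each axis mixes the standardized centroid axis (weight ``spatial_coupling``,
    so the leading recovered gradients emulate left-right / anterior-posterior
    organization) with an independent Gaussian component that fills the volume.
    A full-rank Gaussian cloud is what makes diffusion-map recovery of the
    latent axes near-linear: kernel eigenfunctions over a Gaussian cloud are
    approximately the linear coordinates, ordered by scale.
    """
    xyz = atlas.centroids
    z = (xyz - xyz.mean(0)) / xyz.std(0)
    c = float(config.spatial_coupling)
    dims = []
    for k in range(config.latent_dim):
        noise = rng.standard_normal(atlas.n_regions)
        scale = config.latent_scales[k] if k < len(config.latent_scales) else 0.6 * 0.8 ** (k - 2)
        base = z[:, k] if k < 3 else 0.0
        dims.append(scale * (c * base + np.sqrt(1.0 - c**2) * noise))
    return np.column_stack(dims)


def _radial_displace(latent: np.ndarray, rows: np.ndarray, center: np.ndarray, factor: float) -> None:
    latent[rows] = center + factor * (latent[rows] - center)


def _symmetric_lognormal_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n, n))
    iu = np.triu_indices(n, 1)
    out = np.zeros((n, n))
    out[iu] = z[iu]
    out += out.T
    return np.exp(sd * out)


def _sparsify(w: np.ndarray, density: float, protect: np.ndarray = None) -> np.ndarray:
    """Keep the largest ``density`` fraction of off-diagonal edges (deterministic).

    Edges of the maximum spanning tree over the ``protect`` sub-block are
    always retained, so sparsification cannot disconnect that subgraph.
    """
    if density >= 1.0:
        return w
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    vals = w[iu]
    keep = int(round(density * vals.size))
    if keep < vals.size:
        order = np.argsort(vals, kind="stable")
        cut = vals[order[vals.size - keep]] if keep > 0 else np.inf
        mask = np.zeros_like(w, dtype=bool)
        sel = vals >= cut
        mask[iu[0][sel], iu[1][sel]] = True
        mask |= mask.T
        if protect is not None:
            sub = w[np.ix_(protect, protect)]
            mst = minimum_spanning_tree(-sub).toarray() != 0
            mi, mj = np.nonzero(mst | mst.T)
            mask[protect[mi], protect[mj]] = True
            mask[protect[mj], protect[mi]] = True
        w = np.where(mask, w, 0.0)
    return w


def _cortical_connected(w: np.ndarray, cortical_ids: np.ndarray) -> bool:
    sub = w[np.ix_(cortical_ids, cortical_ids)]
    n_comp, _ = connected_components((sub > 0).astype(np.int8), directed=False)
    return n_comp == 1


def simulate_cohort(config: SimulationConfig) -> ConnectomeCohort:
    """Generate a full cohort with planted effects and a ground-truth record.

    Identical configs (including the seed) yield bit-identical cohorts. With
    ``effect_expand = effect_contract = 0`` and ``subcortical_degree_effect = 1``
    the patient/control labels are exchangeable.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    atlas = make_atlas(config)
    n = atlas.n_regions
    n_subj = config.n_patients + config.n_controls

    latent = _latent_positions(atlas, config, rng)
    diff = atlas.centroids[:, None, :] - atlas.centroids[None, :, :]
    phys_dist = np.sqrt((diff**2).sum(-1))
    dist_kernel = np.exp(-phys_dist / config.distance_decay)

    expand_rows = atlas.regions_in_network(EXPANSION_NETWORK)
    contract_rows = atlas.regions_in_network(CONTRACTION_NETWORK)
    degree_rows = atlas.subcortical_regions_named(DEGREE_EFFECT_STRUCTURES)
    cortical_ids = atlas.cortical_ids

    # covariates drawn for all subjects up-front, independent of group
    groups = np.array(["patient"] * config.n_patients + ["control"] * config.n_controls)
    age = rng.uniform(*config.age_range, size=n_subj).round(1)
    sex = np.where(rng.random(n_subj) < config.sex_ratio_female, "F", "M")
    phases, auras, depression, anxiety = [], [], [], []
    phase_names = list(_PHASE_PROBS)
    phase_p = np.array(list(_PHASE_PROBS.values()))
    phase_p = phase_p / phase_p.sum()
    for g in groups:
        if g == "patient":
            phases.append(phase_names[rng.choice(len(phase_names), p=phase_p)])
            auras.append("yes" if rng.random() < _AURA_PROB else "no")
            depression.append(int(rng.random() < _DEPRESSION_PROB))
            anxiety.append(int(rng.random() < _ANXIETY_PROB))
        else:
            phases.append("none")
            auras.append("none")
            depression.append(0)
            anxiety.append(0)

    matrices = np.empty((n_subj, n, n))
    for s in range(n_subj):
        is_patient = groups[s] == "patient"
        for attempt in range(5):
            g = latent + rng.normal(0.0, config.latent_noise_sd, size=latent.shape)
            if is_patient and (config.effect_expand > 0 or config.effect_contract > 0):
                center = g[cortical_ids].mean(0)
                _radial_displace(g, expand_rows, center, 1.0 + config.effect_expand)
                _radial_displace(g, contract_rows, center, 1.0 - config.effect_contract)
            gdiff = g[:, None, :] - g[None, :, :]
            w = np.exp(-np.sqrt((gdiff**2).sum(-1))) * dist_kernel
            np.fill_diagonal(w, 0.0)
            if config.edge_noise_sd > 0:
                w = w * _symmetric_lognormal_noise(n, config.edge_noise_sd, rng)
            if is_patient and config.subcortical_degree_effect != 1.0:
                f = config.subcortical_degree_effect
                w[degree_rows, :] *= f
                w[:, degree_rows] *= f  # edges between two affected rows get f^2
            w = _sparsify(w, config.density, protect=cortical_ids)
            if _cortical_connected(w, cortical_ids):
                break
            logger.warning("subject %d: disconnected cortical graph, regenerating (attempt %d)", s, attempt + 1)
        else:
            raise RuntimeError(
                f"subject {s}: cortical graph stayed disconnected after 5 attempts; "
                "density/distance_decay parameters are degenerate"
            )
        matrices[s] = w

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n_subj)],
            "group": groups,
            "age": age,
            "sex": sex,
            "phase": phases,
            "aura": auras,
            "depression": depression,
            "anxiety": anxiety,
        }
    )
    truth = {
        "expanded_regions": expand_rows.tolist(),
        "contracted_regions": contract_rows.tolist(),
        "subcortical_increased_regions": degree_rows.tolist(),
        "effect_expand": config.effect_expand,
        "effect_contract": config.effect_contract,
        "subcortical_degree_effect": config.subcortical_degree_effect,
        "latent": latent.tolist(),
        "config": asdict(config),
    }
    return ConnectomeCohort(atlas=atlas, matrices=matrices, subjects=subjects, truth=truth)
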