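"""Synthetic region atlases for connectome simulations.

A :class:`RegionAtlas` mimics the metadata a parcellation scheme provides:
cortical parcels with centroid coordinates, hemisphere, a seven-network
functional community label (visual, somatomotor, dorsal attention, ventral
attention, limbic, frontoparietal, default) and a four-level cortical
hierarchy label (idiotypic, unimodal, heteromodal, paralimbic), plus seven
bilateral subcortical structures (thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NETWORKS7 = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

HIERARCHY4 = ("idiotypic", "unimodal", "heteromodal", "paralimbic")

#: Deterministic network -> hierarchy assignment. Somatomotor parcels are
#: idiotypic (primary) and limbic parcels paralimbic, so radial effects planted
#: by network membership land in a single hierarchy class as well.
NETWORK_TO_HIERARCHY = {
    "visual": "unimodal",
    "somatomotor": "idiotypic",
    "dorsal_attention": "unimodal",
    "ventral_attention": "heteromodal",
    "limbic": "paralimbic",
    "frontoparietal": "heteromodal",
    "default": "heteromodal",
}

SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

# Interior positions for subcortical structures (left hemisphere; right is the
# x-mirror), loosely modeled on typical stereotaxic centroids, arbitrary units.
_SUBCORTICAL_CENTROIDS_LEFT = {
    "thalamus": (-11.0, -18.0, 8.0),
    "caudate": (-13.0, 10.0, 10.0),
    "putamen": (-25.0, 0.0, 0.0),
    "pallidum": (-20.0, -4.0, -1.0),
    "hippocampus": (-28.0, -22.0, -12.0),
    "amygdala": (-24.0, -2.0, -18.0),
    "accumbens": (-9.0, 10.0, -7.0),
}

_ATLAS_COLUMNS = [
    "region_id",
    "name",
    "hemisphere",
    "kind",
    "x",
    "y",
    "z",
    "network7",
    "hierarchy4",
    "subcortical_name",
]


@dataclass
class RegionAtlas:
    """Region metadata table (one row per parcel or subcortical structure)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(_ATLAS_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if not np.array_equal(self.table["region_id"].to_numpy(), np.arange(len(self.table))):
            raise ValueError("region_id must be the contiguous 0-based row index")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def is_cortical(self) -> np.ndarray:
        return (self.table["kind"] == "cortical").to_numpy()

    @property
    def cortical_ids(self) -> np.ndarray:
        return self.table.loc[self.is_cortical, "region_id"].to_numpy()

    @property
    def subcortical_ids(self) -> np.ndarray:
        return self.table.loc[~self.is_cortical, "region_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    def network_labels(self) -> pd.Series:
        """network7 labels of cortical regions, indexed by region_id."""
        cort = self.table[self.is_cortical]
        return cort.set_index("region_id")["network7"]

    def hierarchy_labels(self) -> pd.Series:
        cort = self.table[self.is_cortical]
        return cort.set_index("region_id")["hierarchy4"]

    def cortical_distances(self) -> np.ndarray:
        """Euclidean inter-centroid distances between cortical regions."""
        xyz = self.centroids[self.is_cortical]
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def regions_in_network(self, network: str) -> np.ndarray:
        mask = self.is_cortical & (self.table["network7"] == network).to_numpy()
        return self.table.loc[mask, "region_id"].to_numpy()

    def subcortical_regions_named(self, names) -> np.ndarray:
        mask = self.table["subcortical_name"].isin(list(names)).to_numpy()
        return self.table.loc[mask, "region_id"].to_numpy()


def _hemisphere_shell(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` centroids on a left-hemisphere shell (x < 0)."""
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 0] = -np.abs(pts[:, 0]) - 1e-3  # strictly left of the midline
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * radius


def _contiguous_blocks(n: int, n_blocks: int) -> np.ndarray:
    """Block label per item: ``n_blocks`` consecutive groups, sizes within 1."""
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def make_atlas(config) -> RegionAtlas:
    """Build a mirrored two-hemisphere synthetic atlas from a simulation config.

    Cortical centroids sit on two mirrored hemispheric shells; network labels
    are assigned in spatially contiguous blocks (sorted by azimuth within each
    hemisphere) so each of the seven networks appears in both hemispheres.
    """
    n_cortical = int(config.n_cortical)
    n_subcortical = int(config.n_subcortical)
    if n_cortical % 2 != 0:
        raise ValueError("n_cortical must be even (mirrored hemispheres)")
    if n_cortical < 28:
        raise ValueError("n_cortical must be >= 28 to cover 7 networks x 2 hemispheres with >= 2 regions each")
    if n_subcortical % 2 != 0 or n_subcortical // 2 > len(SUBCORTICAL_STRUCTURES):
        raise ValueError("n_subcortical must be even and at most 14")

    rng = np.random.default_rng(int(config.seed))
    n_hemi = n_cortical // 2
    left = _hemisphere_shell(n_hemi, radius=config.shell_radius, rng=rng)
    # order along the azimuthal angle -> contiguous network neighborhoods
    order = np.argsort(np.arctan2(left[:, 2], left[:, 1]))
    left = left[order]
    right = left.copy()
    right[:, 0] = -right[:, 0]

    blocks = _contiguous_blocks(n_hemi, len(NETWORKS7))
    rows = []
    rid = 0
    for hemi, pts in (("left", left), ("right", right)):
        for k in range(n_hemi):
            net = NETWORKS7[blocks[k]]
            rows.append(
                {
                    "region_id": rid,
                    "name": f"ctx_{'lh' if hemi == 'left' else 'rh'}_{k:03d}",
                    "hemisphere": hemi,
                    "kind": "cortical",
                    "x": pts[k, 0],
                    "y": pts[k, 1],
                    "z": pts[k, 2],
                    "network7": net,
                    "hierarchy4": NETWORK_TO_HIERARCHY[net],
                    "subcortical_name": "",
                }
            )
            rid += 1
    for hemi in ("left", "right"):
        for name in SUBCORTICAL_STRUCTURES[: n_subcortical // 2]:
            x, y, z = _SUBCORTICAL_CENTROIDS_LEFT[name]
            if hemi == "right":
                x = -x
            rows.append(
                {
                    "region_id": rid,
                    "name": f"{'lh' if hemi == 'left' else 'rh'}_{name}",
                    "hemisphere": hemi,
                    "kind": "subcortical",
                    "x": x,
                    "y": y,
                    "z": z,
                    "network7": "",
                    "hierarchy4": "",
                    "subcortical_name": name,
                }
            )
            rid += 1
    return RegionAtlas(pd.DataFrame(rows, columns=_ATLAS_COLUMNS))
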