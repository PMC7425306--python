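"""Bilateral grey-matter parcellation used throughout the package.

The default atlas mirrors a FreeSurfer-style cortical parcellation
(Desikan-Killiany, 34 cortical regions per hemisphere) extended with six
subcortical nuclei and one brainstem-level node per hemisphere, i.e. 41
regions per hemisphere and 82 in total.  Region volumes (mm^3) are drawn
from a seeded log-normal distribution so that volume-normalised edge
weighting downstream is exercised with realistic heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Desikan-Killiany cortical labels (34 per hemisphere)
CORTICAL_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
)

BRAINSTEM_REGIONS: tuple[str, ...] = ("brainstem",)

REGION_SEQUENCE: tuple[str, ...] = (
    CORTICAL_REGIONS + SUBCORTICAL_REGIONS + BRAINSTEM_REGIONS
)

N_PER_HEMISPHERE = len(REGION_SEQUENCE)  # 41
N_TOTAL = 2 * N_PER_HEMISPHERE  # 82

HEMISPHERES = ("left", "right")

_CLASS_OF = {name: "cortical" for name in CORTICAL_REGIONS}
_CLASS_OF.update({name: "subcortical" for name in SUBCORTICAL_REGIONS})
_CLASS_OF.update({name: "brainstem" for name in BRAINSTEM_REGIONS})

# Rough volume scales (mm^3) per node class; log-normal jitter is applied
# around these medians.
_MEDIAN_VOLUME = {"cortical": 8000.0, "subcortical": 3000.0, "brainstem": 5000.0}
_LOG_SIGMA = 0.35


@dataclass(frozen=True)
class Parcellation:
    """Ordered bilateral node table: all left-hemisphere regions, then all
    right-hemisphere regions, with identical region-name sequences."""

    nodes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "node_class", "volume_mm3"}
        missing = required - set(self.nodes.columns)
        if missing:
            raise ValueError(f"node table missing columns: {sorted(missing)}")
        if (self.nodes["volume_mm3"] <= 0).any():
            raise ValueError("volumes must be positive")
        for hemi in HEMISPHERES:
            sub = self.nodes[self.nodes["hemisphere"] == hemi]
            if sub["name"].duplicated().any():
                raise ValueError(f"duplicate region names in {hemi} hemisphere")
        left = self.nodes[self.nodes["hemisphere"] == "left"]["name"].tolist()
        right = self.nodes[self.nodes["hemisphere"] == "right"]["name"].tolist()
        if left != right:
            raise ValueError("hemisphere region sequences differ")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_per_hemisphere(self) -> int:
        return self.n_nodes // 2

    @property
    def volumes(self) -> np.ndarray:
        return self.nodes["volume_mm3"].to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return self.nodes["name"].tolist()

    def hemisphere_index(self, side: str) -> np.ndarray:
        """Positional indices of one hemisphere's nodes, order preserved."""
        if side not in HEMISPHERES:
            raise ValueError(f"side must be one of {HEMISPHERES}, got {side!r}")
        return np.flatnonzero((self.nodes["hemisphere"] == side).to_numpy())

    def node_index(self, name: str, side: str) -> int:
        idx = self.hemisphere_index(side)
        names = self.nodes["name"].to_numpy()[idx]
        where = np.flatnonzero(names == name)
        if len(where) == 0:
            raise KeyError(f"region {name!r} not in {side} hemisphere")
        return int(idx[where[0]])

    def ring_position(self) -> np.ndarray:
        """Within-hemisphere ring coordinate (0..n_hemi-1) for each node.

        Nodes of each hemisphere are laid out on a circle in table order;
        this embedding defines 'distance' (and hence long-range edges) for
        the synthetic generator.
        """
        n_hemi = self.n_per_hemisphere
        return np.concatenate([np.arange(n_hemi), np.arange(n_hemi)])


def make_parcellation(seed: int) -> Parcellation:
    """Build the default 82-node bilateral parcellation with seeded volumes."""
    rng = np.random.default_rng(seed)
    rows = []
    for hemi in HEMISPHERES:
        for name in REGION_SEQUENCE:
            node_class = _CLASS_OF[name]
            vol = float(
                _MEDIAN_VOLUME[node_class] * rng.lognormal(mean=0.0, sigma=_LOG_SIGMA)
            )
            rows.append(
                {
                    "name": name,
                    "hemisphere": hemi,
                    "node_class": node_class,
                    "volume_mm3": vol,
                }
            )
    return Parcellation(nodes=pd.DataFrame(rows))
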