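"""Spatial embedding of the parcellation: node coordinates and distances.

Every network in the pipeline lives on a fixed parcellation whose regions
(nodes) have 3D centroid coordinates in millimetres.  The Euclidean distance
matrix derived from those coordinates is the static "cost" term of the
generative model and the length scale for all edge-length measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["NodeGeometry"]


@dataclass(frozen=True)
class NodeGeometry:
    """Node labels, 3D coordinates (mm) and hemisphere assignment.

    Parameters
    ----------
    node_ids : sequence of str
        Ordered region labels, one per node.
    coords : (N, 3) array
        Region centroid coordinates in mm.
    hemisphere : sequence of {'L', 'R'}
        Hemisphere label per node.

    Notes
    -----
    Coordinates must be pairwise distinct so that the derived distance
    matrix is strictly positive off the diagonal; a zero distance would
    make the distance-penalty kernel ``d**eta`` singular for negative eta.
    """

    node_ids: tuple = field(repr=False)
    coords: np.ndarray = field(repr=False)
    hemisphere: tuple = field(repr=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        node_ids = tuple(str(n) for n in self.node_ids)
        hemisphere = tuple(str(h) for h in self.hemisphere)
        n = len(node_ids)
        if n < 4:
            raise ValueError(f"need at least 4 nodes, got {n}")
        if coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(hemisphere) != n:
            raise ValueError("hemisphere labels must match node count")
        if set(hemisphere) - {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        d = pdist(coords)
        if np.any(d == 0.0):
            raise ValueError("duplicated coordinates: distances must be > 0")
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "hemisphere", hemisphere)
        object.__setattr__(self, "_distances", squareform(d))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def distance_matrix(self) -> np.ndarray:
        """Symmetric Euclidean distance matrix (mm), zero diagonal."""
        return self._distances

    @property
    def hemisphere_mask(self) -> np.ndarray:
        """Boolean (N, N) matrix, True where the pair is intra-hemispheric."""
        h = np.asarray(self.hemisphere)
        return h[:, None] == h[None, :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.node_ids),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "hemisphere": list(self.hemisphere),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NodeGeometry":
        return cls(
            node_ids=tuple(df["node_id"].astype(str)),
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            hemisphere=tuple(df["hemisphere"].astype(str)),
        )

    @classmethod
    def from_tsv(cls, path) -> "NodeGeometry":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))
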