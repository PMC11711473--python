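"""Vectorised binary-graph primitives shared by the growth engine and metrics.

All functions take a dense symmetric 0/1 adjacency matrix (float or int)
with a zero diagonal and are written to be cheap enough to call at every
iteration of network growth.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "degree_vector",
    "common_neighbors",
    "matching_matrix",
    "clustering_vector",
]


def degree_vector(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1)


def common_neighbors(a: np.ndarray) -> np.ndarray:
    """(N, N) count of shared neighbours for each pair (zero diagonal).

    With a zero diagonal, (A @ A)[i, j] never counts i or j themselves,
    so it is exactly |N(i) ∩ N(j) \\ {i, j}|.
    """
    c = a @ a
    np.fill_diagonal(c, 0.0)
    return c


def matching_matrix(a: np.ndarray) -> np.ndarray:
    """Matching index for every pair: shared neighbours over the union of
    neighbourhoods, both excluding the pair itself.

    m_ij = |N(i) ∩ N(j) \\ {i,j}| / |N(i) ∪ N(j) \\ {i,j}|, and 0 when the
    union is empty.  This is the normalised form of the common-neighbour
    ("neighbors") count.
    """
    a = np.asarray(a, dtype=float)
    c = common_neighbors(a)
    deg = a.sum(axis=1)
    union = deg[:, None] + deg[None, :] - 2.0 * a - c
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(union > 0, c / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(m, 0.0)
    return m


def clustering_vector(a: np.ndarray) -> np.ndarray:
    """Binary clustering coefficient per node; 0 for degree < 2."""
    a = np.asarray(a, dtype=float)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * number of triangles
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c
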