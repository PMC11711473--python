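"""Core network containers: binary networks and weighted connectomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import NodeGeometry

__all__ = ["BinaryNetwork", "SubjectCovariates", "WeightedConnectome", "Cohort"]

TERM_CUTOFF_WEEKS = 37.0  # gestational age at birth defining term vs preterm


def _check_square_symmetric(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if np.any(np.diag(m) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    if not np.array_equal(m, m.T):
        raise ValueError(f"{name} must be symmetric")


@dataclass(frozen=True)
class BinaryNetwork:
    """A binarized structural network: symmetric 0/1 adjacency, zero diagonal.

    All topological computation in the pipeline operates on this type.
    """

    adjacency: np.ndarray = field(repr=False)
    geometry: Optional[NodeGeometry] = field(default=None, repr=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.uint8)
        _check_square_symmetric(a, "adjacency")
        if self.geometry is not None and self.geometry.n_nodes != a.shape[0]:
            raise ValueError("geometry size does not match adjacency")
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of node index pairs i < j, lexicographic order."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        present = self.adjacency[i, j] > 0
        return np.column_stack([i[present], j[present]])

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of each present edge (edge_list order)."""
        if self.geometry is None:
            raise ValueError("network has no geometry attached")
        e = self.edge_list()
        return self.geometry.distance_matrix[e[:, 0], e[:, 1]]

    def to_edge_tsv(self, path) -> None:
        e = self.edge_list()
        ids = (
            np.asarray(self.geometry.node_ids)
            if self.geometry is not None
            else np.arange(self.n_nodes).astype(str)
        )
        pd.DataFrame({"node_i": ids[e[:, 0]], "node_j": ids[e[:, 1]]}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject demographics.

    ``pma_weeks`` is postmenstrual age at scan (gestation plus postnatal
    time); ``ga_birth_weeks`` is gestational age at birth.  A subject is
    preterm when born before 37 completed weeks.
    """

    subject_id: str
    pma_weeks: float
    ga_birth_weeks: float
    sex: str
    group: str = ""

    def __post_init__(self):
        if self.ga_birth_weeks > self.pma_weeks:
            raise ValueError("ga_birth_weeks cannot exceed pma_weeks")
        expected = "term" if self.ga_birth_weeks >= TERM_CUTOFF_WEEKS else "preterm"
        if self.group == "":
            object.__setattr__(self, "group", expected)
        elif self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with ga_birth={self.ga_birth_weeks}"
            )


@dataclass(frozen=True)
class WeightedConnectome:
    """Streamline-count connectivity matrix for one subject."""

    subject: SubjectCovariates
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights)
        if np.any(w < 0):
            raise ValueError("streamline counts must be nonnegative")
        if not np.all(w == np.round(w)):
            raise ValueError("streamline counts must be integers")
        w = w.astype(np.int64)
        _check_square_symmetric(w, "weights")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binary_density(self) -> float:
        n = self.n_nodes
        return (self.weights > 0).sum() / (n * (n - 1))


@dataclass(frozen=True)
class Cohort:
    """A set of subjects sharing one parcellation geometry."""

    geometry: NodeGeometry
    subjects: tuple

    def __post_init__(self):
        subjects = tuple(self.subjects)
        if len(subjects) == 0:
            raise ValueError("cohort must contain at least one subject")
        for s in subjects:
            if s.n_nodes != self.geometry.n_nodes:
                raise ValueError("subject matrix size does not match geometry")
        object.__setattr__(self, "subjects", subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def covariates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject.subject_id,
                "pma": s.subject.pma_weeks,
                "ga_birth": s.subject.ga_birth_weeks,
                "sex": s.subject.sex,
                "group": s.subject.group,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)
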