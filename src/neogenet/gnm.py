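"""Generative network growth engine.

Networks are grown edge by edge from a seed network.  At each iteration the
probability that an absent pair (i, j) wires is proportional to

    p_ij ∝ d_ij**eta * (k_ij + eps)**gamma

where ``d_ij`` is the static Euclidean distance between the nodes (the
wiring "cost"; negative eta penalises long connections) and ``k_ij`` is a
topological "value" term recomputed from the current adjacency after every
addition.  Thirteen interchangeable value rules are registered: a pure
spatial baseline (k ≡ 1), homophily rules (common-neighbour count and its
normalised form, the matching index), and pairwise combinations
(avg/min/max/diff/prod) of the endpoints' clustering coefficients or
degrees.

The small offset ``eps`` keeps zero-value pairs reachable: homophily value
is 0 for most pairs early in growth and 0**gamma would freeze the process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from ._matrixops import clustering_vector, degree_vector, matching_matrix, common_neighbors
from .networks import BinaryNetwork

__all__ = [
    "VALUE_RULES",
    "GNMSpec",
    "GrowthTrace",
    "value_matrix",
    "wiring_probabilities",
    "grow_network",
    "derive_seed_network",
]

DEFAULT_EPSILON = 1e-5
DEFAULT_SEED_PREVALENCE = 0.95  # edge kept in the seed if present in >= 95% of subjects


def _pairwise(vec: np.ndarray, op: str) -> np.ndarray:
    x, y = vec[:, None], vec[None, :]
    if op == "avg":
        return (x + y) / 2.0
    if op == "min":
        return np.minimum(x, y)
    if op == "max":
        return np.maximum(x, y)
    if op == "diff":
        return np.abs(x - y)
    if op == "prod":
        return x * y
    raise ValueError(op)


def _make_clu_rule(op: str) -> Callable[[np.ndarray], np.ndarray]:
    def rule(a: np.ndarray) -> np.ndarray:
        return _pairwise(clustering_vector(a), op)

    return rule


def _make_deg_rule(op: str) -> Callable[[np.ndarray], np.ndarray]:
    def rule(a: np.ndarray) -> np.ndarray:
        return _pairwise(degree_vector(a), op)

    return rule


VALUE_RULES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "spatial": lambda a: np.ones_like(np.asarray(a, dtype=float)),
    "neighbors": lambda a: common_neighbors(np.asarray(a, dtype=float)),
    "matching": matching_matrix,
}
for _op in ("avg", "min", "max", "diff", "prod"):
    VALUE_RULES[f"clu-{_op}"] = _make_clu_rule(_op)
    VALUE_RULES[f"deg-{_op}"] = _make_deg_rule(_op)


@dataclass(frozen=True)
class GNMSpec:
    """Wiring rule and exponents of the growth model.

    eta weights the Euclidean-distance cost, gamma the topological value;
    epsilon is the small positive offset added to the value term before
    exponentiation.
    """

    rule: str = "matching"
    eta: float = -1.74
    gamma: float = 0.32
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.rule not in VALUE_RULES:
            raise ValueError(
                f"unknown value rule {self.rule!r}; known: {sorted(VALUE_RULES)}"
            )
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not (np.isfinite(self.eta) and np.isfinite(self.gamma)):
            raise ValueError("eta and gamma must be finite")


@dataclass(frozen=True)
class GrowthTrace:
    """Ordered record of a single growth run.

    ``edges[t]`` is the pair added at iteration t (i < j), ``probs[t]`` its
    wiring probability at the moment of selection and ``lengths[t]`` its
    Euclidean length.  ``seed_adjacency`` plus the edge sequence replays to
    ``adjacency`` exactly.
    """

    spec: GNMSpec
    seed_adjacency: np.ndarray = field(repr=False)
    edges: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)
    lengths: np.ndarray = field(repr=False)
    adjacency: np.ndarray = field(repr=False)

    @property
    def n_iterations(self) -> int:
        return len(self.edges)

    def replay(self) -> np.ndarray:
        a = np.array(self.seed_adjacency, dtype=np.uint8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    def network(self, geometry=None) -> BinaryNetwork:
        return BinaryNetwork(self.adjacency, geometry=geometry)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": np.arange(self.n_iterations),
                "i": self.edges[:, 0] if self.n_iterations else np.array([], int),
                "j": self.edges[:, 1] if self.n_iterations else np.array([], int),
                "prob": self.probs,
                "length": self.lengths,
            }
        )


def value_matrix(rule: str, network) -> np.ndarray:
    """Evaluate a value rule on a binary network, returning the N×N value term."""
    if rule not in VALUE_RULES:
        raise ValueError(f"unknown value rule {rule!r}; known: {sorted(VALUE_RULES)}")
    a = network.adjacency if isinstance(network, BinaryNetwork) else np.asarray(network)
    return VALUE_RULES[rule](np.asarray(a, dtype=float))


def wiring_probabilities(
    distances: np.ndarray,
    k: np.ndarray,
    spec: GNMSpec,
    current_adjacency: np.ndarray,
) -> np.ndarray:
    """Probability of each absent pair wiring next, as a full N×N matrix.

    Scores are d**eta * (k + eps)**gamma over absent off-diagonal pairs,
    normalised to sum to 1 over unordered pairs; present edges and the
    diagonal get probability 0.
    """
    d = np.asarray(distances, dtype=float)
    a = np.asarray(current_adjacency, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    if np.any(d[iu] <= 0):
        raise ValueError("distances must be positive off the diagonal")
    absent = a[iu] == 0
    scores = d[iu] ** spec.eta * (np.asarray(k, float)[iu] + spec.epsilon) ** spec.gamma
    scores = np.where(absent, scores, 0.0)
    total = scores.sum()
    if not total > 0:
        raise ValueError("all wiring scores are zero; no absent pair can be selected")
    p = scores / total
    out = np.zeros((n, n))
    out[iu] = p
    return out + out.T


def grow_network(
    seed,
    distances: np.ndarray,
    spec: GNMSpec,
    m_target: int,
    rng: np.random.Generator,
) -> GrowthTrace:
    """Grow a network from ``seed`` to exactly ``m_target`` edges.

    One absent pair is added per iteration, sampled by inverse-CDF over a
    fixed upper-triangular ordering so runs are reproducible across
    platforms given the same generator state.  The value term is recomputed
    from scratch after every addition.
    """
    seed_a = seed.adjacency if isinstance(seed, BinaryNetwork) else np.asarray(seed)
    a = np.asarray(seed_a, dtype=float).copy()
    d = np.asarray(distances, dtype=float)
    n = a.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match seed network size")
    iu_i, iu_j = np.triu_indices(n, k=1)
    if np.any(d[iu_i, iu_j] <= 0):
        raise ValueError("distances must be positive off the diagonal")
    m_seed = int(a.sum()) // 2
    max_edges = n * (n - 1) // 2
    if m_target < m_seed:
        raise ValueError(f"m_target={m_target} below seed edge count {m_seed}")
    if m_target > max_edges:
        raise ValueError(f"m_target={m_target} exceeds {max_edges} possible edges")

    rule_fn = VALUE_RULES[spec.rule]
    d_eta = d[iu_i, iu_j] ** spec.eta
    absent = a[iu_i, iu_j] == 0
    n_steps = m_target - m_seed

    edges = np.empty((n_steps, 2), dtype=np.int64)
    probs = np.empty(n_steps)
    lengths = np.empty(n_steps)
    for t in range(n_steps):
        k = rule_fn(a)
        scores = d_eta * (k[iu_i, iu_j] + spec.epsilon) ** spec.gamma
        scores[~absent] = 0.0
        cdf = np.cumsum(scores)
        total = cdf[-1]
        if not total > 0:
            raise ValueError("all wiring scores are zero during growth")
        idx = int(np.searchsorted(cdf, rng.random() * total, side="right"))
        idx = min(idx, len(cdf) - 1)
        i, j = int(iu_i[idx]), int(iu_j[idx])
        a[i, j] = a[j, i] = 1.0
        absent[idx] = False
        edges[t] = (i, j)
        probs[t] = scores[idx] / total
        lengths[t] = d[i, j]

    return GrowthTrace(
        spec=spec,
        seed_adjacency=np.asarray(seed_a, dtype=np.uint8).copy(),
        edges=edges,
        probs=probs,
        lengths=lengths,
        adjacency=a.astype(np.uint8),
    )


def derive_seed_network(
    cohort_binary,
    prevalence: float = DEFAULT_SEED_PREVALENCE,
    geometry=None,
) -> BinaryNetwork:
    """Seed network: edges present in at least ``prevalence`` of subjects.

    An empty seed is legal (growth then starts from the empty network).
    """
    nets = list(cohort_binary)
    if not nets:
        raise ValueError("empty cohort")
    stack = np.stack(
        [n.adjacency if isinstance(n, BinaryNetwork) else np.asarray(n) for n in nets]
    ).astype(float)
    frac = stack.mean(axis=0)
    seed = (frac >= prevalence).astype(np.uint8)
    np.fill_diagonal(seed, 0)
    if geometry is None and isinstance(nets[0], BinaryNetwork):
        geometry = nets[0].geometry
    return BinaryNetwork(seed, geometry=geometry)
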