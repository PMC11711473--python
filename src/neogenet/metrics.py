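"""Topological measures of binary networks.

Local measures (per node): degree, betweenness centrality (unnormalised
shortest-path participation), clustering coefficient, nodal edge length
(sum of the Euclidean lengths of the node's connections), local efficiency
and mean matching index.  Global measures: density, maximum modularity from
Newman's spectral community detection with Kernighan–Lin refinement,
characteristic path length (mean finite shortest path), and global
efficiency (mean inverse shortest path, 0 for disconnected pairs).

Rich-club analysis normalises the raw coefficient against degree-preserving
rewired null networks and classifies every edge as rich (both endpoints in
the club), feeder (one endpoint) or local (neither).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._matrixops import clustering_vector, matching_matrix
from .networks import BinaryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "LocalMeasures",
    "GlobalMeasures",
    "RichClubResult",
    "EdgeClassification",
    "LOCAL_MEASURE_NAMES",
    "local_measures",
    "global_measures",
    "betweenness_centrality",
    "modularity_spectral",
    "rewire_preserving_degree",
    "rich_club",
    "classify_edges",
]

LOCAL_MEASURE_NAMES = (
    "degree",
    "clustering",
    "betweenness",
    "nodal_edge_length",
    "local_efficiency",
    "matching",
)

EDGE_CLASSES = ("rich", "feeder", "local")


@dataclass(frozen=True)
class LocalMeasures:
    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    nodal_edge_length: np.ndarray
    local_efficiency: np.ndarray
    matching: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """Stack measures as a (6, N) array in LOCAL_MEASURE_NAMES order."""
        return np.vstack([getattr(self, m) for m in LOCAL_MEASURE_NAMES])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({m: getattr(self, m) for m in LOCAL_MEASURE_NAMES})


@dataclass(frozen=True)
class GlobalMeasures:
    density: float
    modularity_q: float
    characteristic_path_length: float
    global_efficiency: float
    partition: np.ndarray = field(repr=False)
    n_rich: Optional[int] = None
    n_feeder: Optional[int] = None
    n_local: Optional[int] = None
    mean_length_rich: Optional[float] = None
    mean_length_feeder: Optional[float] = None
    mean_length_local: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "density": self.density,
            "modularity_q": self.modularity_q,
            "characteristic_path_length": self.characteristic_path_length,
            "global_efficiency": self.global_efficiency,
        }
        for k in ("n_rich", "n_feeder", "n_local",
                  "mean_length_rich", "mean_length_feeder", "mean_length_local"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def _as_adjacency(network) -> np.ndarray:
    a = network.adjacency if isinstance(network, BinaryNetwork) else np.asarray(network)
    return np.asarray(a, dtype=float)


def betweenness_centrality(network) -> np.ndarray:
    """Unnormalised betweenness on unweighted shortest paths.

    Brandes' algorithm run over all sources simultaneously: the BFS phase
    advances one level per matrix product (sigma accumulates geodesic
    counts), and the dependency accumulation walks the levels backwards.
    Each unordered pair is counted from both endpoints, hence the final
    halving.
    """
    a = _as_adjacency(network)
    n = a.shape[0]
    dist = np.where(np.eye(n, dtype=bool), 0.0, -1.0)  # -1 = unreached
    sigma = np.eye(n)
    frontier = np.eye(n, dtype=bool)
    level = 0
    while frontier.any():
        level += 1
        reach = (sigma * frontier) @ a
        new = (reach > 0) & (dist < 0)
        sigma += np.where(new, reach, 0.0)
        dist[new] = level
        frontier = new
    max_level = int(dist.max())
    delta = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for lev in range(max_level, 0, -1):
            w_mask = dist == lev
            coeff = np.where(w_mask, (1.0 + delta) / np.where(sigma > 0, sigma, 1.0), 0.0)
            contrib = coeff @ a
            delta += np.where(dist == lev - 1, sigma * contrib, 0.0)
    np.fill_diagonal(delta, 0.0)
    return delta.sum(axis=0) / 2.0


def _distance_matrix_hops(a: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf where disconnected."""
    if a.sum() == 0:
        n = a.shape[0]
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def _global_efficiency_from_hops(hops: np.ndarray) -> float:
    n = hops.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / hops[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(network) -> np.ndarray:
    """Per node, the global efficiency of its neighbourhood subgraph."""
    a = _as_adjacency(network)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        out[i] = _global_efficiency_from_hops(_distance_matrix_hops(sub))
    return out


def local_measures(network, distances: Optional[np.ndarray] = None) -> LocalMeasures:
    """All six local measures of a binary network.

    ``distances`` defaults to the network's attached geometry; nodal edge
    length is the sum of Euclidean lengths of the node's edges.
    """
    a = _as_adjacency(network)
    if distances is None:
        if not isinstance(network, BinaryNetwork) or network.geometry is None:
            raise ValueError("distances required when network has no geometry")
        distances = network.geometry.distance_matrix
    d = np.asarray(distances, dtype=float)
    n = a.shape[0]
    m = matching_matrix(a)
    mean_matching = m.sum(axis=1) / max(n - 1, 1)
    return LocalMeasures(
        degree=a.sum(axis=1).astype(int),
        clustering=clustering_vector(a),
        betweenness=betweenness_centrality(a),
        nodal_edge_length=(a * d).sum(axis=1),
        local_efficiency=local_efficiency(a),
        matching=mean_matching,
    )


# ---------------------------------------------------------------------------
# Modularity: Newman spectral bisection with Kernighan-Lin style refinement
# ---------------------------------------------------------------------------

def _kl_refine(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-node flips; each node moved at most once per pass."""
    n = len(s)
    best_s = s.copy()
    best_q = best_s @ bg @ best_s
    improved = True
    while improved:
        improved = False
        s = best_s.copy()
        q = best_q
        moved = np.zeros(n, dtype=bool)
        trial_s, trial_q = s.copy(), q
        for _ in range(n):
            # gain of flipping node v: Q' - Q = -4 s_v * (Bg s)_v + 4 Bg_vv
            bs = bg @ trial_s
            gains = -4.0 * trial_s * bs + 4.0 * np.diag(bg)
            gains[moved] = -np.inf
            v = int(np.argmax(gains))
            trial_s[v] = -trial_s[v]
            moved[v] = True
            trial_q = trial_q + gains[v]
            if trial_q > best_q + 1e-12:
                best_q = trial_q
                best_s = trial_s.copy()
                improved = True
    return best_s


def modularity_spectral(network) -> tuple[float, np.ndarray]:
    """Maximum-modularity partition by recursive spectral bisection.

    Returns (Q, labels).  Deterministic: eigenvectors from ``numpy.linalg.eigh``
    and a fixed sign convention.  Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j).
    """
    a = _as_adjacency(network)
    n = a.shape[0]
    two_m = a.sum()
    labels = np.zeros(n, dtype=int)
    if two_m == 0:
        return 0.0, labels
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / two_m

    next_label = [1]

    def split(nodes: np.ndarray, label: int) -> None:
        if len(nodes) < 2:
            return
        bsub = b[np.ix_(nodes, nodes)]
        bg = bsub - np.diag(bsub.sum(axis=1))
        w, v = np.linalg.eigh(bg)
        lead = v[:, -1]
        if w[-1] <= 1e-10:
            return
        s = np.where(lead >= 0, 1.0, -1.0)
        s = _kl_refine(bg, s)
        dq = s @ bg @ s
        if dq <= 1e-10 or np.all(s == s[0]):
            return
        group2 = nodes[s < 0]
        group1 = nodes[s > 0]
        new = next_label[0]
        next_label[0] += 1
        labels[group2] = new
        split(group1, label)
        split(group2, new)

    split(np.arange(n), 0)
    same = labels[:, None] == labels[None, :]
    q = (b * same).sum() / two_m
    return float(q), labels


def characteristic_path_length(network) -> float:
    """Mean shortest path over connected pairs; NaN if no pair is connected."""
    a = _as_adjacency(network)
    hops = _distance_matrix_hops(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = hops[off][np.isfinite(hops[off])]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def global_efficiency(network) -> float:
    a = _as_adjacency(network)
    return _global_efficiency_from_hops(_distance_matrix_hops(a))


def global_measures(
    network,
    distances: Optional[np.ndarray] = None,
    rich_nodes: Optional[Sequence[int]] = None,
) -> GlobalMeasures:
    """Global topology; edge-class counts/lengths included when ``rich_nodes``
    is given (requires distances or attached geometry)."""
    a = _as_adjacency(network)
    n = a.shape[0]
    q, partition = modularity_spectral(a)
    gm = dict(
        density=float(a.sum() / (n * (n - 1))) if n > 1 else 0.0,
        modularity_q=q,
        partition=partition,
        characteristic_path_length=characteristic_path_length(a),
        global_efficiency=global_efficiency(a),
    )
    if rich_nodes is not None:
        if distances is None:
            if isinstance(network, BinaryNetwork) and network.geometry is not None:
                distances = network.geometry.distance_matrix
            else:
                raise ValueError("distances required for edge classification")
        cls = classify_edges(a, rich_nodes, distances)
        gm.update(
            n_rich=cls.counts["rich"],
            n_feeder=cls.counts["feeder"],
            n_local=cls.counts["local"],
            mean_length_rich=cls.mean_lengths["rich"],
            mean_length_feeder=cls.mean_lengths["feeder"],
            mean_length_local=cls.mean_lengths["local"],
        )
    return GlobalMeasures(**gm)


# ---------------------------------------------------------------------------
# Degree-preserving rewiring and rich-club analysis
# ---------------------------------------------------------------------------

def rewire_preserving_degree(
    network,
    iterations_per_edge: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> BinaryNetwork:
    """Double-edge-swap randomisation; exact degree preservation.

    Attempts ``iterations_per_edge * m`` successful swaps with a retry
    budget; if the budget is exhausted (e.g. star graphs admit no swap) the
    network is returned with however many swaps were achieved.
    """
    rng = np.random.default_rng() if rng is None else rng
    a = _as_adjacency(network).astype(np.uint8).copy()
    geometry = network.geometry if isinstance(network, BinaryNetwork) else None
    i_idx, j_idx = np.triu_indices(a.shape[0], k=1)
    present = a[i_idx, j_idx] > 0
    edges = list(zip(i_idx[present].tolist(), j_idx[present].tolist()))
    m = len(edges)
    if m < 2:
        return BinaryNetwork(a, geometry=geometry)
    target = iterations_per_edge * m
    budget = 40 * target
    done = 0
    attempts = 0
    while done < target and attempts < budget:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        aa, bb = edges[e1]
        cc, dd = edges[e2]
        if rng.random() < 0.5:
            cc, dd = dd, cc
        # propose (aa, dd) and (cc, bb)
        if len({aa, bb, cc, dd}) < 4:
            continue
        if a[aa, dd] or a[cc, bb]:
            continue
        a[aa, bb] = a[bb, aa] = 0
        a[cc, dd] = a[dd, cc] = 0
        a[aa, dd] = a[dd, aa] = 1
        a[cc, bb] = a[bb, cc] = 1
        edges[e1] = (min(aa, dd), max(aa, dd))
        edges[e2] = (min(cc, bb), max(cc, bb))
        done += 1
    if done < target:
        logger.debug("rewiring stopped at %d/%d swaps", done, target)
    return BinaryNetwork(a, geometry=geometry)


def rich_club_coefficients(network) -> tuple[np.ndarray, np.ndarray]:
    """Raw rich-club coefficient phi(k) for each degree level k.

    phi(k) = 2 E_k / (N_k (N_k - 1)) over the subgraph of nodes with degree
    strictly greater than k; levels with fewer than two such nodes are
    excluded.  Returns (k_levels, phi).
    """
    a = _as_adjacency(network)
    deg = a.sum(axis=1)
    kmax = int(deg.max()) if deg.size else 0
    ks, phis = [], []
    for k in range(1, kmax):
        nodes = np.flatnonzero(deg > k)
        if len(nodes) < 2:
            continue
        sub = a[np.ix_(nodes, nodes)]
        e_k = sub.sum() / 2.0
        ks.append(k)
        phis.append(2.0 * e_k / (len(nodes) * (len(nodes) - 1)))
    return np.array(ks, dtype=int), np.array(phis)


@dataclass(frozen=True)
class RichClubResult:
    k_levels: np.ndarray
    phi: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    phi_norm: np.ndarray
    p_values: np.ndarray
    clubs: tuple            # one (k_range, node_tuple) per contiguous significant run
    k_star: Optional[int]   # smallest k of the selected (largest) club
    rich_nodes: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_levels,
                "phi": self.phi,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "phi_norm": self.phi_norm,
                "p": self.p_values,
            }
        )


def rich_club(
    network,
    n_nulls: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    iterations_per_edge: int = 10,
) -> RichClubResult:
    """Normalised rich-club detection against degree-preserving nulls.

    For each degree level k the empirical one-sided p is the fraction of
    null networks whose phi is at least the observed phi.  Every significant
    level k defines a candidate club (all nodes with degree > k); contiguous
    significant runs are reported for inspection.  The selected rich club is
    the largest candidate comprising a *minority* of nodes (at most half the
    network): a "club" containing most of the network is no elite at all —
    at low k the null phi is almost fully determined by the degree sequence,
    so its variance collapses and fraction-of-a-percent excesses come out
    "significant".
    """
    rng = np.random.default_rng() if rng is None else rng
    a = _as_adjacency(network)
    deg = a.sum(axis=1)
    ks, phi = rich_club_coefficients(a)
    nulls = np.full((n_nulls, len(ks)), np.nan)
    for r in range(n_nulls):
        null_net = rewire_preserving_degree(a, iterations_per_edge, rng)
        ks_n, phi_n = rich_club_coefficients(null_net.adjacency)
        # identical degree sequence => identical defined k levels
        nulls[r] = phi_n if len(ks_n) == len(ks) else np.interp(ks, ks_n, phi_n)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.where(null_mean > 0, phi / np.where(null_mean > 0, null_mean, 1), np.nan)
    p_values = (nulls >= phi[None, :]).mean(axis=0)
    significant = p_values < alpha

    clubs = []
    run = []
    for idx, sig in enumerate(significant):
        if sig:
            run.append(idx)
        elif run:
            clubs.append(run)
            run = []
    if run:
        clubs.append(run)
    club_records = []
    for run in clubs:
        k_lo = int(ks[run[0]])
        nodes = tuple(int(v) for v in np.flatnonzero(deg > k_lo))
        club_records.append((tuple(int(ks[i]) for i in run), nodes))

    candidates = [
        (int(k), tuple(int(v) for v in np.flatnonzero(deg > k)))
        for k in ks[significant]
    ]
    minority = [c for c in candidates if 2 <= len(c[1]) <= a.shape[0] // 2]
    if minority:
        k_star, rich_nodes = max(minority, key=lambda c: (len(c[1]), -c[0]))
    else:
        k_star = None
        rich_nodes = ()
    return RichClubResult(
        k_levels=ks,
        phi=phi,
        null_mean=null_mean,
        null_sd=null_sd,
        phi_norm=phi_norm,
        p_values=p_values,
        clubs=tuple(club_records),
        k_star=k_star,
        rich_nodes=rich_nodes,
    )


@dataclass(frozen=True)
class EdgeClassification:
    edges: np.ndarray = field(repr=False)       # (m, 2)
    labels: np.ndarray = field(repr=False)      # (m,) of {rich, feeder, local}
    lengths: np.ndarray = field(repr=False)
    counts: dict = field(default_factory=dict)
    mean_lengths: dict = field(default_factory=dict)


def classify_edges(network, rich_nodes, distances) -> EdgeClassification:
    """Partition edges into rich / feeder / local classes.

    rich: both endpoints in the rich club; feeder: exactly one; local:
    neither.  Mean length of an empty class is reported as NaN.
    """
    a = _as_adjacency(network)
    d = np.asarray(distances, dtype=float)
    rich = np.zeros(a.shape[0], dtype=bool)
    rich_list = list(rich_nodes)
    if rich_list:
        rich[np.asarray(rich_list, dtype=int)] = True
    i, j = np.triu_indices(a.shape[0], k=1)
    present = a[i, j] > 0
    ei, ej = i[present], j[present]
    n_rich_ends = rich[ei].astype(int) + rich[ej].astype(int)
    labels = np.array(EDGE_CLASSES)[2 - n_rich_ends]
    lengths = d[ei, ej]
    counts, mean_lengths = {}, {}
    for cls in EDGE_CLASSES:
        mask = labels == cls
        counts[cls] = int(mask.sum())
        mean_lengths[cls] = float(lengths[mask].mean()) if mask.any() else float("nan")
        if counts[cls] == 0:
            logger.debug("edge class %r is empty", cls)
    return EdgeClassification(
        edges=np.column_stack([ei, ej]),
        labels=labels,
        lengths=lengths,
        counts=counts,
        mean_lengths=mean_lengths,
    )
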