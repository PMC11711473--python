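"""From weighted streamline-count cohorts to the binary networks analysed.

The construction path mirrors standard connectome thresholding for sparse
binary analyses: (1) a group consensus mask removes edges absent in most
subjects (tractography false positives), (2) either an absolute
streamline-count threshold chosen to give a target *mean* density across
the cohort, or a per-subject proportional threshold giving every subject an
*exact* target density, and (3) a group-representative consensus network
built so its connection-length distribution matches the subjects' (plain
prevalence ranking over-selects short edges).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .networks import BinaryNetwork, Cohort, WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdReport",
    "consensus_mask",
    "apply_mask",
    "threshold_absolute",
    "threshold_to_density",
    "find_absolute_threshold_for_mean_density",
    "build_consensus_network",
    "round_half_away",
]

DEFAULT_CONSENSUS_PROPORTION = 0.60
DEFAULT_ABSOLUTE_THRESHOLD = 325
DEFAULT_TARGET_DENSITY = 0.10
DEFAULT_N_DISTANCE_BINS = 10


def round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6); numpy rounds half
    to even, which would make fractional edge targets depend on parity."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class ThresholdReport:
    """Per-subject densities before/after each thresholding step."""

    steps: list = field(default_factory=list)

    def record(self, step: str, subject_ids, densities_before, densities_after, value=None):
        self.steps.append(
            {
                "step": step,
                "value": value,
                "subjects": list(subject_ids),
                "density_before": [float(d) for d in densities_before],
                "density_after": [float(d) for d in densities_after],
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps({"steps": self.steps}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def consensus_mask(
    cohort: Cohort,
    proportion: float = DEFAULT_CONSENSUS_PROPORTION,
    strict: bool = False,
) -> BinaryNetwork:
    """Group consensus mask: edge kept iff present (weight > 0) in at least
    ``proportion`` of subjects (strictly more when ``strict``)."""
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    presence = np.stack([(s.weights > 0) for s in cohort]).mean(axis=0)
    mask = presence > proportion if strict else presence >= proportion
    mask = mask.astype(np.uint8)
    np.fill_diagonal(mask, 0)
    return BinaryNetwork(mask, geometry=cohort.geometry)


def apply_mask(cohort: Cohort, mask: BinaryNetwork) -> Cohort:
    """Multiply every subject's weights by the mask."""
    subjects = tuple(
        WeightedConnectome(s.subject, s.weights * mask.adjacency) for s in cohort
    )
    return Cohort(geometry=cohort.geometry, subjects=subjects)


def threshold_absolute(
    connectome: WeightedConnectome,
    min_count: int = DEFAULT_ABSOLUTE_THRESHOLD,
    geometry=None,
) -> BinaryNetwork:
    """Binarize: edge retained iff its streamline count is >= ``min_count``
    (and nonzero, so min_count=0 keeps exactly the nonzero edges)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    w = connectome.weights
    a = ((w >= min_count) & (w > 0)).astype(np.uint8)
    return BinaryNetwork(a, geometry=geometry)


def threshold_to_density(
    connectome: WeightedConnectome,
    target_density: float = DEFAULT_TARGET_DENSITY,
    geometry=None,
) -> BinaryNetwork:
    """Keep the strongest edges up to an exact target density.

    The edge count is round-half-away-from-zero of ``target * N(N-1)/2``.
    Ties at the cutoff break deterministically: higher weight first, then
    lexicographic (i, j).
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    w = connectome.weights
    n = w.shape[0]
    m_target = round_half_away(target_density * n * (n - 1) / 2)
    i, j = np.triu_indices(n, k=1)
    weights = w[i, j]
    nonzero = weights > 0
    if nonzero.sum() < m_target:
        raise ValueError(
            f"subject {connectome.subject.subject_id!r}: only {int(nonzero.sum())} "
            f"nonzero edges, cannot reach target of {m_target}"
        )
    order = np.lexsort((j, i, -weights))        # primary: weight desc; then (i, j)
    order = order[weights[order] > 0][:m_target]
    a = np.zeros((n, n), dtype=np.uint8)
    a[i[order], j[order]] = 1
    return BinaryNetwork(a + a.T, geometry=geometry)


def find_absolute_threshold_for_mean_density(
    cohort: Cohort,
    target_mean_density: float = DEFAULT_TARGET_DENSITY,
) -> tuple[int, float]:
    """Smallest integer count threshold whose cohort-mean density is at most
    the target.  Mean density is non-increasing in the threshold, so a
    bisection over candidate integer thresholds suffices.  Returns
    (threshold, achieved mean density)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def mean_density(t: int) -> float:
        return float(
            np.mean([threshold_absolute(s, t).density for s in cohort.subjects])
        )

    lo = 0
    if mean_density(lo) <= target_mean_density:
        return 0, mean_density(0)
    hi = int(max(s.weights.max() for s in cohort)) + 1
    if mean_density(hi) > target_mean_density:
        raise ValueError("target mean density unreachable at any threshold")
    # invariant: mean_density(lo) > target >= mean_density(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mean_density(mid) <= target_mean_density:
            hi = mid
        else:
            lo = mid
    return hi, mean_density(hi)


def build_consensus_network(
    cohort_binary,
    distances: np.ndarray,
    n_bins: int = DEFAULT_N_DISTANCE_BINS,
    hemispheres=None,
    geometry=None,
) -> BinaryNetwork:
    """Distance-binned group consensus network.

    Edges that appear in any subject are pooled and binned by Euclidean
    length (equal-count bins; intra- and inter-hemispheric edges binned
    separately when hemisphere labels are available).  Within each bin the
    most prevalent edges are selected, as many as the rounded mean per-bin
    edge count across subjects.  This preserves the subjects' connection-
    length distribution, which plain prevalence ranking distorts towards
    short edges.
    """
    nets = [
        n.adjacency if isinstance(n, BinaryNetwork) else np.asarray(n)
        for n in cohort_binary
    ]
    if not nets:
        raise ValueError("empty cohort")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if geometry is None:
        for n in cohort_binary:
            if isinstance(n, BinaryNetwork) and n.geometry is not None:
                geometry = n.geometry
                break
    if hemispheres is None and geometry is not None:
        hemispheres = geometry.hemisphere
    stack = np.stack(nets).astype(float)
    n_sub, n_nodes, _ = stack.shape
    d = np.asarray(distances, dtype=float)
    prevalence = stack.mean(axis=0)
    iu = np.triu_indices(n_nodes, k=1)
    out = np.zeros((n_nodes, n_nodes), dtype=np.uint8)

    if hemispheres is not None:
        h = np.asarray(hemispheres)
        intra = (h[iu[0]] == h[iu[1]])
        groups = [intra, ~intra]
    else:
        groups = [np.ones(len(iu[0]), dtype=bool)]

    for group_mask in groups:
        gi, gj = iu[0][group_mask], iu[1][group_mask]
        candidate = prevalence[gi, gj] > 0
        ci, cj = gi[candidate], gj[candidate]
        if len(ci) == 0:
            continue
        lengths = d[ci, cj]
        # equal-count distance bins over the candidate edges of this group
        edges_per_bin_quantiles = np.quantile(lengths, np.linspace(0, 1, n_bins + 1))
        bin_idx = np.clip(
            np.searchsorted(edges_per_bin_quantiles[1:-1], lengths, side="right"),
            0,
            n_bins - 1,
        )
        for b in range(n_bins):
            sel = bin_idx == b
            if not sel.any():
                continue
            bi, bj = ci[sel], cj[sel]
            # mean number of subject edges falling in this bin
            in_bin = stack[:, bi, bj].sum(axis=1)
            target = round_half_away(float(in_bin.mean()))
            if target <= 0:
                continue
            if target > sel.sum():
                logger.warning(
                    "distance bin %d wants %d edges but has only %d candidates",
                    b, target, int(sel.sum()),
                )
                target = int(sel.sum())
            prev = prevalence[bi, bj]
            order = np.lexsort((bj, bi, -prev))[:target]
            out[bi[order], bj[order]] = 1

    out = out + out.T
    return BinaryNetwork(out, geometry=geometry)
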