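"""Representative term vs preterm growth experiment.

Two batches of growth runs are launched at the group-representative
exponents (defaults: preterm eta=-1.85, gamma=0.34; term eta=-1.74,
gamma=0.32), every edge addition is recorded, and each edge is classified
against a rich-node set frozen from the cohort consensus network before any
simulation.  Per iteration the experiment tracks cumulative rich / feeder /
local edge counts and cumulative mean Euclidean connection lengths, overall
and per class, averaged over runs.  Group contrasts use run-level
permutation rather than model-based inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gnm import GNMSpec, grow_network
from .metrics import EDGE_CLASSES
from .networks import BinaryNetwork

__all__ = ["GroupModelConfig", "IterationSummary", "GroupComparison", "run_group", "compare_groups"]


@dataclass(frozen=True)
class GroupModelConfig:
    eta_term: float = -1.74
    gamma_term: float = 0.32
    eta_preterm: float = -1.85
    gamma_preterm: float = 0.34
    n_runs: int = 1000
    m_target: int = 400
    rule: str = "matching"
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for v in (self.eta_term, self.gamma_term, self.eta_preterm, self.gamma_preterm):
            if not np.isfinite(v):
                raise ValueError("parameters must be finite")

    def spec_for(self, group: str) -> GNMSpec:
        if group == "term":
            return GNMSpec(self.rule, self.eta_term, self.gamma_term, self.epsilon)
        if group == "preterm":
            return GNMSpec(self.rule, self.eta_preterm, self.gamma_preterm, self.epsilon)
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class IterationSummary:
    """Run-resolved growth statistics for one group.

    Arrays are (n_runs, n_iterations).  Counts are cumulative and include
    the seed network's edges, so rich + feeder + local equals the total
    edge count at every iteration.  Cumulative mean lengths are over all
    edges present at the iteration (seed included); per-class means are NaN
    while a class is empty.
    """

    group: str
    config: GroupModelConfig
    m_seed: int
    counts: dict = field(repr=False)        # class -> (n_runs, T) cumulative counts
    cum_mean_length: dict = field(repr=False)  # class + "all" -> (n_runs, T)
    added_lengths: np.ndarray = field(repr=False)  # (n_runs, T) length of edge added at t

    @property
    def n_runs(self) -> int:
        return self.added_lengths.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.added_lengths.shape[1]

    def final_mean_length(self) -> np.ndarray:
        """Per-run cumulative mean connection length at the final iteration."""
        return self.cum_mean_length["all"][:, -1]

    def final_counts(self, cls: str) -> np.ndarray:
        return self.counts[cls][:, -1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: group, run, iteration, class, count, cum_mean_length."""
        runs, iters = np.meshgrid(
            np.arange(self.n_runs), np.arange(self.n_iterations), indexing="ij"
        )
        frames = []
        for cls in EDGE_CLASSES:
            frames.append(
                pd.DataFrame(
                    {
                        "group": self.group,
                        "run": runs.ravel(),
                        "iteration": iters.ravel(),
                        "class": cls,
                        "count": self.counts[cls].ravel(),
                        "cum_mean_length": self.cum_mean_length[cls].ravel(),
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "group": self.group,
                    "run": runs.ravel(),
                    "iteration": iters.ravel(),
                    "class": "all",
                    "count": sum(self.counts[c] for c in EDGE_CLASSES).ravel(),
                    "cum_mean_length": self.cum_mean_length["all"].ravel(),
                }
            )
        )
        return pd.concat(frames, ignore_index=True)

    def mean_curves(self) -> pd.DataFrame:
        """Mean and SD over runs, per iteration and class (NaN while a
        class has no edges in any run)."""
        rows = []
        for cls in list(EDGE_CLASSES) + ["all"]:
            counts = (
                sum(self.counts[c] for c in EDGE_CLASSES)
                if cls == "all"
                else self.counts[cls]
            )
            lengths = self.cum_mean_length[cls]
            any_data = np.isfinite(lengths).any(axis=0)
            lmean = np.full(lengths.shape[1], np.nan)
            lsd = np.full(lengths.shape[1], np.nan)
            if any_data.any():
                lmean[any_data] = np.nanmean(lengths[:, any_data], axis=0)
                lsd[any_data] = np.nanstd(lengths[:, any_data], axis=0)
            rows.append(
                pd.DataFrame(
                    {
                        "group": self.group,
                        "iteration": np.arange(self.n_iterations),
                        "class": cls,
                        "count_mean": counts.mean(axis=0),
                        "count_sd": counts.std(axis=0),
                        "length_mean": lmean,
                        "length_sd": lsd,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _classify_pairs(i: np.ndarray, j: np.ndarray, rich: np.ndarray) -> np.ndarray:
    """0=rich, 1=feeder, 2=local for each (i, j) pair."""
    return 2 - (rich[i].astype(int) + rich[j].astype(int))


def run_group(
    config: GroupModelConfig,
    group: str,
    distances: np.ndarray,
    rich_nodes,
    rng: np.random.Generator,
    seed_network=None,
) -> IterationSummary:
    """Run ``config.n_runs`` growth simulations for one group and reduce the
    traces to per-iteration class statistics.

    ``rich_nodes`` must be derived once (from the cohort consensus network)
    before any simulation and is shared by both groups.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    seed_a = (
        np.zeros((n, n), dtype=np.uint8)
        if seed_network is None
        else (
            seed_network.adjacency
            if isinstance(seed_network, BinaryNetwork)
            else np.asarray(seed_network)
        )
    )
    rich = np.zeros(n, dtype=bool)
    rich_list = list(rich_nodes)
    if rich_list:
        rich[np.asarray(rich_list, dtype=int)] = True
    spec = config.spec_for(group)
    m_seed = int(seed_a.sum()) // 2
    t_steps = config.m_target - m_seed
    if t_steps < 0:
        raise ValueError("m_target below seed edge count")

    # seed contribution, identical across runs
    si, sj = np.triu_indices(n, k=1)
    seed_present = seed_a[si, sj] > 0
    seed_cls = _classify_pairs(si[seed_present], sj[seed_present], rich)
    seed_len = d[si, sj][seed_present]
    seed_counts = np.array([(seed_cls == c).sum() for c in range(3)], dtype=float)
    seed_len_sums = np.array(
        [seed_len[seed_cls == c].sum() for c in range(3)], dtype=float
    )

    counts = {cls: np.zeros((config.n_runs, t_steps)) for cls in EDGE_CLASSES}
    cum_mean = {cls: np.full((config.n_runs, t_steps), np.nan) for cls in EDGE_CLASSES}
    cum_mean["all"] = np.full((config.n_runs, t_steps), np.nan)
    added = np.zeros((config.n_runs, t_steps))

    for r in range(config.n_runs):
        trace = grow_network(seed_a, d, spec, config.m_target, rng)
        cls_seq = _classify_pairs(trace.edges[:, 0], trace.edges[:, 1], rich)
        added[r] = trace.lengths
        for c, cls_name in enumerate(EDGE_CLASSES):
            mask = cls_seq == c
            cum_count = seed_counts[c] + np.cumsum(mask)
            counts[cls_name][r] = cum_count
            len_sum = seed_len_sums[c] + np.cumsum(np.where(mask, trace.lengths, 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                cum_mean[cls_name][r] = np.where(cum_count > 0, len_sum / np.maximum(cum_count, 1), np.nan)
        total_count = seed_counts.sum() + np.arange(1, t_steps + 1)
        total_len = seed_len_sums.sum() + np.cumsum(trace.lengths)
        cum_mean["all"][r] = total_len / total_count

    return IterationSummary(
        group=group,
        config=config,
        m_seed=m_seed,
        counts=counts,
        cum_mean_length=cum_mean,
        added_lengths=added,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Term-minus-preterm difference curves and permutation summaries."""

    diff_curves: pd.DataFrame = field(repr=False)
    final_length_diff: float
    final_length_p: float
    final_count_diff: dict
    n_permutations: int


def compare_groups(
    summary_term: IterationSummary,
    summary_preterm: IterationSummary,
    n_permutations: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> GroupComparison:
    """Contrast the two groups per iteration.

    Difference curves are term minus preterm means; the permutation p-value
    tests the final cumulative mean length difference against the null of
    exchangeable runs (two-sided).
    """
    if summary_term.n_iterations != summary_preterm.n_iterations:
        raise ValueError("summaries must share m_target / iteration count")
    if summary_term.m_seed != summary_preterm.m_seed:
        raise ValueError("summaries must share the seed network")
    rng = np.random.default_rng() if rng is None else rng

    t_curves = summary_term.mean_curves().set_index(["class", "iteration"])
    p_curves = summary_preterm.mean_curves().set_index(["class", "iteration"])
    diff = pd.DataFrame(
        {
            "count_diff": t_curves["count_mean"] - p_curves["count_mean"],
            "length_diff": t_curves["length_mean"] - p_curves["length_mean"],
        }
    ).reset_index()

    x = summary_term.final_mean_length()
    y = summary_preterm.final_mean_length()
    obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n_x = len(x)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[:n_x].mean() - perm[n_x:].mean()
        if abs(stat) >= abs(obs):
            count += 1
    p_val = (count + 1) / (n_permutations + 1)

    final_count_diff = {
        cls: float(
            summary_term.final_counts(cls).mean()
            - summary_preterm.final_counts(cls).mean()
        )
        for cls in EDGE_CLASSES
    }
    return GroupComparison(
        diff_curves=diff,
        final_length_diff=obs,
        final_length_p=p_val,
        final_count_diff=final_count_diff,
        n_permutations=n_permutations,
    )
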