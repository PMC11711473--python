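"""End-to-end orchestration: synthesize -> threshold -> metrics -> fit -> group models.

Every stage writes plain-text artifacts into the run directory and records
them (with SHA-256 checksums), together with all seeds and parameters, in
``manifest.json``; a rerun with the same configuration reproduces every
artifact byte for byte.  All constants of the analysis (consensus
proportion, absolute threshold, target density, seed prevalence, grid
bounds, null counts, run counts, alpha) are named configuration defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import construction, fitting, gnm, metrics
from .cohort import SyntheticCohortSpec, generate_cohort, read_cohort, write_cohort
from .group import GroupModelConfig, compare_groups, run_group
from .model import GenerativeNetworkModel
from .networks import Cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_cohort", "compute_metrics_tables"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    output_dir: str
    input_dir: Optional[str] = None                 # read a cohort instead of synthesizing
    synthetic: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    consensus_proportion: float = construction.DEFAULT_CONSENSUS_PROPORTION
    absolute_threshold: Optional[int] = None        # None -> search for target mean density
    target_density: float = construction.DEFAULT_TARGET_DENSITY
    thresholding: tuple = ("absolute", "density")   # the two parallel analyses
    seed_prevalence: float = gnm.DEFAULT_SEED_PREVALENCE
    rule: str = "matching"
    grid_n_eta: int = 20
    grid_n_gamma: int = 20
    eta_bounds: tuple = fitting.NARROW_GRID_BOUNDS[0]
    gamma_bounds: tuple = fitting.NARROW_GRID_BOUNDS[1]
    fit_subjects: Optional[int] = None              # fit only the first k subjects
    rich_club_nulls: int = 1000
    rich_club_alpha: float = 0.05
    group_runs: int = 1000
    consensus_bins: int = construction.DEFAULT_N_DISTANCE_BINS
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticCohortSpec(**d["synthetic"])
        for key in ("thresholding", "eta_bounds", "gamma_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def compute_metrics_tables(
    binaries: dict,
    cohort: Cohort,
    rich_nodes,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-subject (subject x measure) and per-node tables."""
    d = cohort.geometry.distance_matrix
    subject_rows, node_frames = [], []
    for sid, net in binaries.items():
        gm = metrics.global_measures(net, d, rich_nodes=rich_nodes)
        for measure, value in gm.to_dict().items():
            subject_rows.append({"subject_id": sid, "measure": measure, "value": value})
        lm = metrics.local_measures(net, d)
        nf = lm.to_frame()
        nf.insert(0, "node_id", list(cohort.geometry.node_ids))
        nf.insert(0, "subject_id", sid)
        node_frames.append(nf)
    return pd.DataFrame(subject_rows), pd.concat(node_frames, ignore_index=True)


def summarize_cohort(metrics_table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-group summaries of every measure, plus measure-vs-age
    columns; deliberately no inferential statistics."""
    if metrics_table.empty or covariates.empty:
        raise ValueError("empty metrics table or covariates")
    merged = metrics_table.merge(covariates, on="subject_id", how="left")
    missing = merged["group"].isna()
    if missing.any():
        logger.warning("dropping %d rows with missing covariates", int(missing.sum()))
        merged = merged[~missing]
    rows = []
    for (measure, group), sub in merged.groupby(["measure", "group"]):
        v = sub["value"].astype(float)
        pma = sub["pma"].astype(float)
        ok = np.isfinite(v)
        rows.append(
            {
                "measure": measure,
                "group": group,
                "n": int(ok.sum()),
                "mean": float(v[ok].mean()) if ok.any() else np.nan,
                "sd": float(v[ok].std(ddof=1)) if ok.sum() > 1 else np.nan,
                "r_pma": float(np.corrcoef(pma[ok], v[ok])[0, 1])
                if ok.sum() > 2 and v[ok].std() > 0 and pma[ok].std() > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
        "artifacts": {},
    }
    root_ss = np.random.SeedSequence(config.rng_seed)
    ss_rich, ss_fit, ss_group = root_ss.spawn(3)

    def register(stage: str, *paths: Path):
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
        manifest["stages"].setdefault(stage, []).extend(
            str(p.relative_to(out)) for p in paths
        )

    # --- stage 1: cohort -------------------------------------------------
    if config.input_dir is not None:
        cohort = read_cohort(config.input_dir)
        manifest["stages"]["cohort"] = [f"loaded from {config.input_dir}"]
    else:
        cohort = generate_cohort(config.synthetic)
        cohort_dir = out / "cohort"
        write_cohort(cohort, cohort_dir)
        register(
            "cohort",
            cohort_dir / "coordinates.tsv",
            cohort_dir / "covariates.csv",
            *sorted((cohort_dir / "matrices").glob("*.txt")),
        )
    d = cohort.geometry.distance_matrix
    covariates = cohort.covariates_frame()

    # --- stage 2: thresholding ------------------------------------------
    report = construction.ThresholdReport()
    ids = [s.subject.subject_id for s in cohort]
    raw_density = [s.binary_density() for s in cohort]
    mask = construction.consensus_mask(cohort, config.consensus_proportion)
    masked = construction.apply_mask(cohort, mask)
    masked_density = [s.binary_density() for s in masked]
    report.record("consensus_mask", ids, raw_density, masked_density,
                  value=config.consensus_proportion)

    analyses = {}
    if "absolute" in config.thresholding:
        if config.absolute_threshold is None:
            thr, achieved = construction.find_absolute_threshold_for_mean_density(
                masked, config.target_density
            )
        else:
            thr = config.absolute_threshold
            achieved = None
        nets = {
            s.subject.subject_id: construction.threshold_absolute(
                s, thr, geometry=cohort.geometry
            )
            for s in masked
        }
        report.record("absolute", ids, masked_density,
                      [nets[i].density for i in ids], value=int(thr))
        analyses["absolute"] = nets
        manifest["stages"]["absolute_threshold"] = [
            {"threshold": int(thr), "achieved_mean_density": achieved}
        ]
    if "density" in config.thresholding:
        nets = {
            s.subject.subject_id: construction.threshold_to_density(
                s, config.target_density, geometry=cohort.geometry
            )
            for s in masked
        }
        report.record("density", ids, masked_density,
                      [nets[i].density for i in ids], value=config.target_density)
        analyses["density"] = nets
    rpt_path = out / "threshold_report.json"
    report.to_json(rpt_path)
    register("threshold", rpt_path)

    # --- stage 3: consensus network, rich club, metrics ------------------
    primary = analyses.get("absolute", next(iter(analyses.values())))
    consensus = construction.build_consensus_network(
        list(primary.values()), d, n_bins=config.consensus_bins,
        geometry=cohort.geometry,
    )
    cons_path = out / "consensus_edges.tsv"
    consensus.to_edge_tsv(cons_path)
    register("consensus", cons_path)

    rc = metrics.rich_club(
        consensus,
        n_nulls=config.rich_club_nulls,
        alpha=config.rich_club_alpha,
        rng=np.random.default_rng(ss_rich),
    )
    rc_path = out / "rich_club.csv"
    rc.to_frame().to_csv(rc_path, index=False)
    register("rich_club", rc_path)
    manifest["stages"]["rich_club"] = [
        {"k_star": rc.k_star, "n_rich_nodes": len(rc.rich_nodes)}
    ]

    for name, nets in analyses.items():
        subj_tbl, node_tbl = compute_metrics_tables(nets, cohort, rc.rich_nodes)
        p1 = out / f"metrics_{name}_subject.csv"
        p2 = out / f"metrics_{name}_node.csv"
        subj_tbl.to_csv(p1, index=False)
        node_tbl.to_csv(p2, index=False)
        register("metrics", p1, p2)
        summary = summarize_cohort(subj_tbl, covariates)
        p3 = out / f"summary_{name}.csv"
        summary.to_csv(p3, index=False)
        register("summary", p3)

    # --- stage 4: per-subject fits ---------------------------------------
    seed_net = gnm.derive_seed_network(
        list(primary.values()), config.seed_prevalence, geometry=cohort.geometry
    )
    seed_path = out / "seed_edges.tsv"
    seed_net.to_edge_tsv(seed_path)
    register("seed", seed_path)

    grid = fitting.make_grid(
        config.eta_bounds, config.gamma_bounds, config.grid_n_eta, config.grid_n_gamma
    )
    n_fit = config.fit_subjects or len(cohort)
    fit_rows, land_frames = [], []
    fit_seed_root = int(ss_fit.generate_state(1)[0] % (2**31))
    for k, s in enumerate(list(cohort)[:n_fit]):
        sid = s.subject.subject_id
        net = primary[sid]
        seed_use = seed_net if seed_net.n_edges <= net.n_edges else None
        mdl = GenerativeNetworkModel(
            net, geometry=cohort.geometry, rule=config.rule, seed_network=seed_use
        )
        res = mdl.fit(grid=grid, seed=fit_seed_root + k)
        fit_rows.append(
            {
                "subject_id": sid,
                "eta": res.params["eta"],
                "gamma": res.params["gamma"],
                "energy": res.energy,
                "tf_dissimilarity": res.tf_dissimilarity(),
            }
        )
        land = res.landscape.copy()
        land.insert(0, "subject_id", sid)
        land_frames.append(land)
    fits = pd.DataFrame(fit_rows)
    p_fit = out / "fits.csv"
    fits.to_csv(p_fit, index=False)
    p_land = out / "landscapes.csv"
    pd.concat(land_frames, ignore_index=True).to_csv(p_land, index=False)
    register("fit", p_fit, p_land)

    # --- stage 5: group experiment ---------------------------------------
    group_cfg = GroupModelConfig(
        n_runs=config.group_runs,
        m_target=max(seed_net.n_edges, int(np.median([n.n_edges for n in primary.values()]))),
        rule=config.rule,
    )
    rng_group = np.random.default_rng(ss_group)
    term = run_group(group_cfg, "term", d, rc.rich_nodes, rng_group, seed_network=seed_net)
    preterm = run_group(group_cfg, "preterm", d, rc.rich_nodes, rng_group, seed_network=seed_net)
    cmp = compare_groups(term, preterm, rng=rng_group)
    p_group = out / "group_experiment.csv"
    pd.concat([term.mean_curves(), preterm.mean_curves()], ignore_index=True).to_csv(
        p_group, index=False
    )
    register("group", p_group)
    manifest["stages"]["group_comparison"] = [
        {
            "final_length_diff_term_minus_preterm": cmp.final_length_diff,
            "final_length_p": cmp.final_length_p,
            "final_count_diff": cmp.final_count_diff,
        }
    ]

    manifest["seeds"] = {"root": config.rng_seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
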