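"""End-to-end orchestration: simulate -> build -> metrics -> stats -> report.

One :class:`RunConfig` drives every stage with explicit seeds; the output
is a machine-readable JSON report whose schema ships with the package
(``report_schema()``).  Desk-scale defaults (null ensembles of 100,
permutation counts of 500) keep a full run tractable on one CPU;
``paper_scale=True`` switches to the full 1000-null / 5000-permutation
analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import connectome as cx
from . import group_stats as gs
from . import metrics as me
from . import nbs as nb
from .lesion_sim import LesionSimConfig, WSConfig, run_experiment
from .synthetic import Cohort, sample_cohort, write_cohort

logger = logging.getLogger("connectolesion")

__all__ = ["RunConfig", "run_all", "report_schema", "validate_report",
           "cohort_connectomes", "hemisphere_observations"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"
    # cohort
    n_patients: int = 17
    n_controls: int = 21
    n_left_lesions: int = 8
    # densities
    kappas: list[float] = field(default_factory=cx.sweep_kappas)
    strength_kappa: float = 0.5  # fixed density of the local analyses
    # statistics
    n_nulls: int = 100
    n_perm: int = 500
    nbs_t: float = 3.1
    alpha: float = 0.05
    # lesion simulation
    ws_n_nodes: int = 41
    ws_k: int = 10
    ws_rewire_p: float = 0.25
    lesion_q: float = 0.5
    # stage toggles
    run_q50: bool = True
    run_mtpc: bool = True
    run_nodes: bool = True
    run_nbs: bool = True
    run_clinical: bool = True
    run_lesion_sim: bool = True
    write_cohort_files: bool = False
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if self.paper_scale:
            self.n_nulls = 1000
            self.n_perm = 5000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Cohort -> observations plumbing
# ---------------------------------------------------------------------------

def cohort_connectomes(cohort: Cohort) -> dict[str, cx.Connectome]:
    """Volume-normalised whole-brain connectome per subject."""
    parc = cohort.parcellation
    return {
        s.id: cx.weights_from_counts(s.counts, parc.volumes, nodes=parc.nodes)
        for s in cohort.subjects
    }


def hemisphere_observations(
    cohort: Cohort, conns: dict[str, cx.Connectome]
) -> tuple[pd.DataFrame, list[cx.Connectome]]:
    """One row and one 41-node network per subject-hemisphere.

    Lesion status is ipsilesional for a patient's lesioned side,
    contralesional for the other side, healthy for controls.
    """
    rows, nets = [], []
    for s in cohort.subjects:
        for side in ("left", "right"):
            if s.group == "patient":
                status = "ipsilesional" if side == s.lesion.side else "contralesional"
            else:
                status = "healthy"
            rows.append({"subject_id": s.id, "side": side, "lesion_status": status})
            nets.append(cx.hemisphere_submatrix(conns[s.id], side))
    return pd.DataFrame(rows), nets


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _mtpc_to_dict(res: gs.MTPCResult) -> dict:
    return {
        "kappas": res.kappas,
        "statistic": res.statistic,
        "a_crit": res.a_crit,
        "clusters": [list(c) for c in res.clusters],
        "cluster_aucs": res.cluster_aucs,
        "null_mean_auc": res.null_mean_auc,
        "significant": res.significant,
        "n_perm": res.n_perm,
    }


def _lesion_model_to_dict(res: gs.LesionModelResult) -> dict:
    return {
        "lambda2": res.lambda2,
        "omnibus_p": res.omnibus_p,
        "f_stat": res.f_stat,
        "f_p": res.f_p,
        "interaction_p": res.interaction_p,
        "shapiro_p": res.shapiro_p,
        "means": dict(res.means) if res.means is not None else {},
        "posthoc": res.posthoc.to_dict(orient="records"),
        "degenerate": res.degenerate,
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _metric_curves(
    obs: pd.DataFrame,
    nets: list[cx.Connectome],
    reference: cx.Connectome,
    cfg: RunConfig,
) -> dict[str, np.ndarray]:
    """Per-observation GGP curves over the density sweep.

    Returns arrays of shape (n_obs, n_kappas) for normalised efficiency,
    normalised clustering and modularity.
    """
    n_obs, n_k = len(obs), len(cfg.kappas)
    eff = np.empty((n_obs, n_k))
    clu = np.empty((n_obs, n_k))
    qmod = np.empty((n_obs, n_k))
    masks = [cx.density_mask(reference, k) for k in cfg.kappas]
    for i, net in enumerate(nets):
        for j, mask in enumerate(masks):
            m = cx.apply_mask(net, mask)
            spec = me.NullEnsembleSpec(
                n_nulls=cfg.n_nulls, seed=cfg.seed + 7919 * i + 104729 * j
            )
            nm = me.normalized_global_metrics(m, spec)
            eff[i, j] = nm["efficiency_norm"]
            clu[i, j] = nm["clustering_norm"]
            q, _ = me.modularity(m, n_restarts=5, seed=cfg.seed + i + j)
            qmod[i, j] = q
    return {"efficiency_norm": eff, "clustering_norm": clu, "modularity": qmod}


def run_all(cfg: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute every enabled stage in dependency order; return the report."""
    t_start = time.time()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    logger.info("stage=simulate seed=%d", cfg.seed)
    if cohort is None:
        cohort = sample_cohort(
            n_patients=cfg.n_patients,
            n_controls=cfg.n_controls,
            n_left_lesions=cfg.n_left_lesions,
            seed=cfg.seed,
        )
    if cfg.write_cohort_files:
        write_cohort(cohort, out_dir / "cohort")

    logger.info("stage=build")
    conns = cohort_connectomes(cohort)
    obs, nets = hemisphere_observations(cohort, conns)
    healthy_sel = obs["lesion_status"] == "healthy"
    healthy_hemis = [nets[i] for i in np.flatnonzero(healthy_sel)]
    ref_hemi = cx.group_average(healthy_hemis)
    mask_fixed = cx.density_mask(ref_hemi, cfg.strength_kappa)
    masked_nets = [cx.apply_mask(n, mask_fixed) for n in nets]

    if cfg.run_q50:
        logger.info("stage=q50")
        df = obs.copy()
        df["value"] = [me.q50(n) for n in masked_nets]
        res = gs.fit_lesion_model(df)
        report["stages"]["q50"] = _lesion_model_to_dict(res)

    if cfg.run_mtpc:
        logger.info("stage=mtpc n_nulls=%d n_perm=%d", cfg.n_nulls, cfg.n_perm)
        curves = _metric_curves(obs, nets, ref_hemi, cfg)
        mtpc_report = {}
        for metric, mat in curves.items():
            per_metric = {}
            for side in ("left", "right"):
                sel = (obs["side"] == side).to_numpy()
                per_metric[side] = _mtpc_to_dict(
                    gs.mtpc(
                        mat[sel],
                        obs.loc[sel, "lesion_status"],
                        obs.loc[sel, "subject_id"],
                        cfg.kappas,
                        n_perm=cfg.n_perm,
                        alpha=cfg.alpha,
                        seed=cfg.seed + 13,
                    )
                )
            per_metric["pooled_residual"] = _mtpc_to_dict(
                gs.pooled_residual_mtpc(
                    mat,
                    obs["side"],
                    obs["lesion_status"],
                    obs["subject_id"],
                    cfg.kappas,
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=cfg.seed + 17,
                )
            )
            mtpc_report[metric] = per_metric
        report["stages"]["mtpc"] = mtpc_report

    if cfg.run_nodes:
        logger.info("stage=node_mass_univariate")
        strengths = np.vstack([me.node_strength(n) for n in masked_nets])
        names = cohort.parcellation.nodes["name"][: cohort.parcellation.n_per_hemisphere]
        node_table = gs.mass_univariate_nodes(
            strengths, obs, node_names=list(names), alpha=cfg.alpha
        )
        report["stages"]["node_mass_univariate"] = {
            "bonferroni_threshold": node_table.attrs["bonferroni_threshold"],
            "nodes": node_table.to_dict(orient="records"),
        }

    if cfg.run_nbs:
        logger.info("stage=nbs t=%.2f", cfg.nbs_t)
        pat_idx = np.flatnonzero((obs["lesion_status"] == "ipsilesional").to_numpy())
        group_a = [masked_nets[i] for i in pat_idx]
        # one hemisphere per control, alternating sides for balance
        ctrl_ids = [s.id for s in cohort.controls]
        group_b = []
        for j, cid in enumerate(ctrl_ids):
            side = "left" if j % 2 == 0 else "right"
            k = np.flatnonzero(
                ((obs["subject_id"] == cid) & (obs["side"] == side)).to_numpy()
            )[0]
            group_b.append(masked_nets[k])
        comps = nb.nbs_test(
            group_a, group_b, t_threshold=cfg.nbs_t,
            n_perm=cfg.n_perm, direction="A<B", seed=cfg.seed + 23,
        )
        names = list(
            cohort.parcellation.nodes["name"][: cohort.parcellation.n_per_hemisphere]
        )
        report["stages"]["nbs"] = {
            "t_threshold": cfg.nbs_t,
            "components": [
                {
                    "extent": c.extent,
                    "fwer_p": c.fwer_p,
                    "edges": [[names[i], names[j]] for i, j in c.edges],
                }
                for c in comps
            ],
        }

    if cfg.run_clinical:
        logger.info("stage=clinical")
        pats = cohort.patients
        ipsi_q50 = []
        for s in pats:
            sel = (obs["subject_id"] == s.id) & (obs["side"] == s.lesion.side)
            ipsi_q50.append(me.q50(masked_nets[int(np.flatnonzero(sel.to_numpy())[0])]))
        clin = {}
        for score_name, values in (
            ("grip_delta", [s.grip_delta for s in pats]),
            ("uefm", [s.uefm for s in pats]),
        ):
            try:
                clin[score_name] = gs.clinical_regression(ipsi_q50, values)
            except ValueError as exc:
                clin[score_name] = {"error": str(exc)}
        report["stages"]["clinical"] = clin

    if cfg.run_lesion_sim:
        logger.info("stage=lesion_sim")
        sim = run_experiment(
            ws=WSConfig(n_nodes=cfg.ws_n_nodes, k=cfg.ws_k, rewire_p=cfg.ws_rewire_p),
            lesion=LesionSimConfig(removal_q=cfg.lesion_q, n_nulls=cfg.n_nulls),
            seed=cfg.seed + 29,
        )
        report["stages"]["lesion_sim"] = {
            "tests": sim["tests"],
            "table": sim["table"].to_dict(orient="records"),
        }

    report["wall_time_s"] = time.time() - t_start
    report = _jsonable(report)
    validate_report(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("done wall_time=%.1fs", report["wall_time_s"])
    return report


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

class _ReportModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    config: dict
    stages: dict
    wall_time_s: float


def report_schema() -> dict:
    """JSON schema of the run report."""
    return _ReportModel.model_json_schema()


def validate_report(report: dict) -> None:
    """Raise if a report does not conform to the published schema."""
    _ReportModel.model_validate(report)
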