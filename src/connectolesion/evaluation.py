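"""Study-level evaluation runs: calibration and planted-truth recovery.

These routines execute the pipeline's statistical stages on many
simulated datasets to measure operating characteristics — family-wise
error of the permutation procedures, type-I error of the mixed model,
recovery of the planted lesion pattern on default synthetic cohorts, and
the direction of the Watts-Strogatz lesion experiment.  They back both
the acceptance test-suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import connectome as cx
from . import group_stats as gs
from . import metrics as me
from . import nbs as nb
from .lesion_sim import LesionSimConfig, WSConfig, run_experiment
from .pipeline import cohort_connectomes, hemisphere_observations
from .synthetic import DEFAULT_TARGET_REGIONS, sample_cohort

MOTOR_DEFICIT_REGIONS = ("precentral", "postcentral", "thalamus", "pallidum", "putamen")


# ---------------------------------------------------------------------------
# Calibration on exchangeable (null) data
# ---------------------------------------------------------------------------

def _null_observation_frame(rng, n_patients=17, n_controls=21, subject_sd=0.5):
    rows = []
    for i in range(n_patients):
        re_ = rng.normal(0, subject_sd)
        lesion_side = "left" if i % 2 == 0 else "right"
        for side in ("left", "right"):
            st = "ipsilesional" if side == lesion_side else "contralesional"
            rows.append({"subject_id": f"p{i}", "side": side,
                         "lesion_status": st, "value": rng.normal() + re_})
    for i in range(n_controls):
        re_ = rng.normal(0, subject_sd)
        for side in ("left", "right"):
            rows.append({"subject_id": f"c{i}", "side": side,
                         "lesion_status": "healthy", "value": rng.normal() + re_})
    return pd.DataFrame(rows)


def nbs_fwer_calibration(
    n_sims: int = 100, n_perm: int = 200, alpha: float = 0.05, seed: int = 0,
    n_nodes: int = 41, n_a: int = 17, n_b: int = 21, t_threshold: float = 3.1,
) -> float:
    """Fraction of exchangeable two-group datasets where NBS reports any
    component with FWER p below alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for s in range(n_sims):
        base = np.abs(cx.symmetrize(rng.uniform(0.5, 1.5, (n_nodes, n_nodes))))
        np.fill_diagonal(base, 0)
        group_a = [np.abs(base + cx.symmetrize(rng.normal(0, 0.2, base.shape)))
                   for _ in range(n_a)]
        group_b = [np.abs(base + cx.symmetrize(rng.normal(0, 0.2, base.shape)))
                   for _ in range(n_b)]
        for m in group_a + group_b:
            np.fill_diagonal(m, 0)
        res = nb.nbs_test(group_a, group_b, t_threshold=t_threshold,
                          n_perm=n_perm, direction="A<B", seed=seed + 7 * s + 1)
        rejections += any(c.fwer_p < alpha for c in res)
    return rejections / n_sims


def mtpc_fwer_calibration(
    n_sims: int = 100, n_perm: int = 200, alpha: float = 0.05, seed: int = 0,
    kappas: list[float] | None = None,
) -> float:
    """Family-wise rejection rate of MTPC on exchangeable curves."""
    kappas = kappas if kappas is not None else cx.sweep_kappas()
    rng = np.random.default_rng(seed)
    rejections = 0
    for s in range(n_sims):
        df = _null_observation_frame(rng)
        curves = rng.normal(0, 1, (len(df), len(kappas)))
        res = gs.mtpc(curves, df["lesion_status"], df["subject_id"], kappas,
                      n_perm=n_perm, alpha=alpha, seed=seed + 13 * s + 1)
        rejections += res.significant
    return rejections / n_sims


def mixed_model_type1(
    n_sims: int = 200, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the lesion-status omnibus on null cohorts."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        res = gs.fit_lesion_model(_null_observation_frame(rng))
        rejections += res.omnibus_p < alpha
    return rejections / n_sims


# ---------------------------------------------------------------------------
# Planted-truth recovery on default synthetic cohorts
# ---------------------------------------------------------------------------

def analyze_planted_cohort(
    seed: int,
    n_nulls: int = 30,
    nbs_n_perm: int = 200,
    run_nbs: bool = True,
    strength_kappa: float = 0.5,
) -> dict:
    """One default cohort through q50, normalized GGPs, node tests and NBS.

    Patients contribute their ipsilesional hemisphere; controls one
    hemisphere each (alternating sides).  Returns per-seed outcomes used
    to score recovery of the planted lesion pattern.
    """
    cohort = sample_cohort(seed=seed)
    parc = cohort.parcellation
    conns = cohort_connectomes(cohort)
    obs, nets = hemisphere_observations(cohort, conns)
    healthy_idx = np.flatnonzero((obs["lesion_status"] == "healthy").to_numpy())
    ref = cx.group_average([nets[i] for i in healthy_idx])
    mask = cx.density_mask(ref, strength_kappa)
    masked = [cx.apply_mask(n, mask) for n in nets]

    ipsi_idx = np.flatnonzero((obs["lesion_status"] == "ipsilesional").to_numpy())
    ctrl_ids = [s.id for s in cohort.controls]
    ctrl_pick = []
    for j, cid in enumerate(ctrl_ids):
        side = "left" if j % 2 == 0 else "right"
        k = np.flatnonzero(
            ((obs["subject_id"] == cid) & (obs["side"] == side)).to_numpy()
        )[0]
        ctrl_pick.append(int(k))

    # q50 deficit
    q_ipsi = [me.q50(masked[i]) for i in ipsi_idx]
    q_ctrl = [me.q50(masked[i]) for i in ctrl_pick]
    tt = sps.ttest_ind(q_ipsi, q_ctrl)
    out = {
        "q50_ipsi_mean": float(np.mean(q_ipsi)),
        "q50_control_mean": float(np.mean(q_ctrl)),
        "q50_p": float(tt.pvalue),
        "q50_deficit": bool(np.mean(q_ipsi) < np.mean(q_ctrl)),
    }

    # normalized GGPs at the fixed density
    def ggp(i: int, tag: int) -> tuple[float, float, float]:
        # coarser weight-placement granularity: adequate for group contrasts
        spec = me.NullEnsembleSpec(
            n_nulls=n_nulls, seed=seed * 1000 + tag, assignment_chunks=100
        )
        nm = me.normalized_global_metrics(masked[i], spec)
        q, _ = me.modularity(masked[i], n_restarts=5, seed=seed * 1000 + tag)
        return nm["efficiency_norm"], nm["clustering_norm"], q

    pat = np.array([ggp(i, t) for t, i in enumerate(ipsi_idx)])
    ctl = np.array([ggp(i, 500 + t) for t, i in enumerate(ctrl_pick)])
    out["d_efficiency_norm"] = float(pat[:, 0].mean() - ctl[:, 0].mean())
    out["d_clustering_norm"] = float(pat[:, 1].mean() - ctl[:, 1].mean())
    out["d_modularity"] = float(pat[:, 2].mean() - ctl[:, 2].mean())

    # mass-univariate node strengths (all 76 hemisphere observations)
    strengths = np.vstack([me.node_strength(n) for n in masked])
    names = list(parc.nodes["name"][: parc.n_per_hemisphere])
    table = gs.mass_univariate_nodes(strengths, obs, node_names=names)
    flagged = set(table.loc[table["significant"], "node"])
    out["flagged_nodes"] = sorted(flagged)
    out["motor_regions_flagged"] = bool(set(MOTOR_DEFICIT_REGIONS) <= flagged)

    if run_nbs:
        comps = nb.nbs_test(
            [masked[i] for i in ipsi_idx],
            [masked[i] for i in ctrl_pick],
            t_threshold=3.1, n_perm=nbs_n_perm, direction="A<B",
            seed=seed * 1000 + 77,
        )
        sig = [c for c in comps if c.fwer_p < 0.05]
        overlap = False
        if sig:
            targets = {names.index(r) for r in DEFAULT_TARGET_REGIONS if r in names}
            overlap = any(
                (i in targets or j in targets) for i, j in sig[0].edges
            )
        out["nbs_significant"] = bool(sig)
        out["nbs_overlaps_planted"] = bool(overlap)
        out["nbs_extent"] = sig[0].extent if sig else 0
    return out


def planted_truth_recovery(
    n_seeds: int = 20, n_nulls: int = 30, nbs_seeds: int = 5, seed0: int = 0
) -> dict:
    """Aggregate planted-lesion recovery across seeded cohorts."""
    per_seed = [
        analyze_planted_cohort(
            seed0 + s, n_nulls=n_nulls, run_nbs=(s < nbs_seeds)
        )
        for s in range(n_seeds)
    ]
    nbs_runs = [r for r in per_seed if "nbs_significant" in r]
    return {
        "per_seed": per_seed,
        "q50_deficit_rate": float(np.mean([r["q50_deficit"] for r in per_seed])),
        "q50_signif_rate": float(
            np.mean([r["q50_p"] < 0.01 and r["q50_deficit"] for r in per_seed])
        ),
        "mean_d_efficiency_norm": float(
            np.mean([r["d_efficiency_norm"] for r in per_seed])
        ),
        "mean_d_clustering_norm": float(
            np.mean([r["d_clustering_norm"] for r in per_seed])
        ),
        "mean_d_modularity": float(np.mean([r["d_modularity"] for r in per_seed])),
        "motor_recovery_rate": float(
            np.mean([r["motor_regions_flagged"] for r in per_seed])
        ),
        "nbs_overlap_rate": float(
            np.mean([r["nbs_significant"] and r["nbs_overlaps_planted"]
                     for r in nbs_runs])
        )
        if nbs_runs
        else np.nan,
    }


# ---------------------------------------------------------------------------
# Lesion-simulation replication
# ---------------------------------------------------------------------------

def lesion_sim_replicates(
    n_replicates: int = 20, n_nulls: int = 100, seed0: int = 0, removal_q: float = 0.5
) -> dict:
    """Directional reproduction of the long-range lesion experiment.

    Per replicate: lower normalized efficiency, higher normalized
    clustering and higher modularity in the lesioned arm, each at
    p < 0.005 (Welch).
    """
    hits = {"efficiency_norm": 0, "clustering_norm": 0, "modularity": 0}
    all_three = 0
    rows = []
    for r in range(n_replicates):
        out = run_experiment(
            ws=WSConfig(),
            lesion=LesionSimConfig(removal_q=removal_q, n_nulls=n_nulls),
            seed=seed0 + r,
        )
        ok = {}
        for metric, t in out["tests"].items():
            expected_sign = -1 if metric == "efficiency_norm" else 1
            ok[metric] = (np.sign(t["difference"]) == expected_sign
                          and t["p"] < 0.005)
            hits[metric] += ok[metric]
        all_three += all(ok.values())
        rows.append({m: out["tests"][m]["difference"] for m in hits} |
                    {f"{m}_p": out["tests"][m]["p"] for m in hits})
    return {
        "table": pd.DataFrame(rows),
        "rates": {m: hits[m] / n_replicates for m in hits},
        "all_directions_rate": all_three / n_replicates,
    }
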