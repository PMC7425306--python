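"""Group-level statistics for hemisphere-wise connectome summaries.

The central design compares three lesion-status levels — ipsilesional,
contralesional and healthy — on per-hemisphere network summaries, with
each subject contributing two hemispheres.  Inference uses a linear
mixed-effects model (fixed effects: hemisphere side, lesion status;
random intercept per subject), likelihood-ratio omnibus tests, Tukey-
adjusted post-hoc mean separation, and a Shapiro-Wilk residual check.

Density-swept global graph parameters are tested with the multi-threshold
permutation correction (MTPC): a statistic-by-density curve is compared
against the permutation distribution of its maximum across densities,
and supra-critical clusters are additionally required to exceed the mean
supra-critical cluster AUC of the permutations, so both the magnitude and
the persistence of an effect across network densities count.

Local node-strength changes use mass-univariate mixed models with
Bonferroni correction (0.05 divided by the number of regions), and
clinical associations use ordinary least-squares regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "LesionStatusModel",
    "LesionModelResult",
    "MTPCResult",
    "fit_lesion_model",
    "mtpc",
    "pooled_residual_mtpc",
    "mass_univariate_nodes",
    "clinical_regression",
]

STATUS_LEVELS = ("healthy", "contralesional", "ipsilesional")


# ---------------------------------------------------------------------------
# Mixed-effects lesion-status model
# ---------------------------------------------------------------------------

@dataclass
class LesionModelResult:
    """Fitted lesion-status contrast on per-hemisphere observations."""

    lambda2: float  # likelihood-ratio statistic for the lesion-status omnibus
    omnibus_p: float
    f_stat: float  # Wald-F approximation of the same omnibus
    f_p: float
    interaction_lr: float
    interaction_p: float
    used_interaction: bool
    posthoc: pd.DataFrame = field(repr=False)
    shapiro_p: float = np.nan
    means: pd.Series = field(default=None, repr=False)
    n_obs: int = 0
    n_subjects: int = 0
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Lesion-status mixed model",
            f"  observations: {self.n_obs}  subjects: {self.n_subjects}",
            f"  side x status interaction: LR={self.interaction_lr:.3f},"
            f" p={self.interaction_p:.4f}"
            f" ({'kept' if self.used_interaction else 'dropped'})",
            f"  omnibus lesion status: Lambda2={self.lambda2:.3f},"
            f" p={self.omnibus_p:.4g}  (Wald F={self.f_stat:.2f}, p={self.f_p:.4g})",
            f"  Shapiro-Wilk residual p: {self.shapiro_p:.4f}",
            "  post-hoc (Tukey-adjusted):",
        ]
        for _, row in self.posthoc.iterrows():
            lines.append(
                f"    {row['contrast']:<32s} diff={row['estimate']:+.4f}"
                f"  p={row['p_tukey']:.4g}"
            )
        return "\n".join(lines)


class LesionStatusModel:
    """Mixed-effects model of a per-hemisphere summary value.

    ``data`` needs columns ``subject_id``, ``side`` (left/right),
    ``lesion_status`` (healthy/contralesional/ipsilesional) and ``value``.
    Optional extra fixed effects (e.g. age, sex) can be named in
    ``covariates``.
    """

    def __init__(self, data: pd.DataFrame, covariates: tuple[str, ...] = ()):
        required = {"subject_id", "side", "lesion_status", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        statuses = set(data["lesion_status"].unique())
        if not statuses <= set(STATUS_LEVELS):
            raise ValueError(f"unknown lesion status levels: {statuses - set(STATUS_LEVELS)}")
        if len(statuses) < 2:
            raise ValueError("need at least two lesion-status levels")
        self.data = data.reset_index(drop=True).copy()
        self.covariates = tuple(covariates)
        counts = data.groupby("lesion_status")["value"].count()
        if (counts < 3).any():
            warnings.warn("fewer than 3 observations in some lesion-status cell")

    @classmethod
    def from_observations(cls, observations: pd.DataFrame, **kw) -> "LesionStatusModel":
        return cls(observations, **kw)

    def _formula(self, interaction: bool, status: bool = True) -> str:
        base = "value ~ C(side)"
        if status and interaction:
            base = "value ~ C(side) * C(lesion_status)"
        elif status:
            base += " + C(lesion_status)"
        for cov in self.covariates:
            base += f" + {cov}"
        return base

    def _fit(self, formula: str):
        # fit on the standardized response: likelihood ratios and p-values
        # are scale-invariant and the optimizer is far better conditioned
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, self._zdata, groups=self._zdata["subject_id"])
            last_exc: Exception | None = None
            # the subject variance can sit on the boundary; try a cascade of
            # optimizers before giving up
            for method in ("bfgs", "lbfgs", "powell", "nm"):
                try:
                    return model.fit(reml=False, method=method)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
            raise last_exc

    def fit(
        self, alpha_interaction: float = 0.05, test_interaction: bool = True
    ) -> LesionModelResult:
        data = self.data
        if np.var(data["value"].to_numpy()) < 1e-30:
            warnings.warn("degenerate (zero-variance) response; no effect estimable")
            return LesionModelResult(
                lambda2=0.0, omnibus_p=1.0, f_stat=0.0, f_p=1.0,
                interaction_lr=0.0, interaction_p=1.0, used_interaction=False,
                posthoc=pd.DataFrame(columns=["contrast", "estimate", "se", "t", "p_tukey"]),
                shapiro_p=np.nan,
                means=data.groupby("lesion_status")["value"].mean(),
                n_obs=len(data), n_subjects=data["subject_id"].nunique(),
                degenerate=True,
            )
        levels = [s for s in STATUS_LEVELS if s in set(data["lesion_status"])]
        two_sides = data["side"].nunique() > 1

        self._scale = float(data["value"].std(ddof=0)) or 1.0
        self._zdata = data.copy()
        self._zdata["value"] = (
            data["value"] - data["value"].mean()
        ) / self._scale

        res_add = self._fit(self._formula(interaction=False))
        inter_lr, inter_p, used_inter = 0.0, 1.0, False
        res_final = res_add
        if test_interaction and two_sides and len(levels) > 1:
            try:
                res_int = self._fit(self._formula(interaction=True))
                inter_lr = max(0.0, 2.0 * (res_int.llf - res_add.llf))
                df_int = res_int.df_modelwc - res_add.df_modelwc
                inter_p = float(sps.chi2.sf(inter_lr, max(df_int, 1)))
                if inter_p < alpha_interaction:
                    used_inter = True
                    res_final = res_int
            except Exception:  # singular interaction design
                pass

        res_null = self._fit(self._formula(interaction=False, status=False))
        lam2 = max(0.0, 2.0 * (res_add.llf - res_null.llf))
        df_stat = len(levels) - 1
        omnibus_p = float(sps.chi2.sf(lam2, df_stat))

        # Wald-F approximation on the status coefficients
        names = list(res_add.params.index)
        sel = [i for i, nm in enumerate(names) if "lesion_status" in nm and ":" not in nm]
        f_stat, f_p = np.nan, np.nan
        if sel:
            beta = res_add.params.values[sel]
            cov = np.asarray(res_add.cov_params())[np.ix_(sel, sel)]
            try:
                w = float(beta @ np.linalg.solve(cov, beta))
                f_stat = w / len(sel)
                df2 = data["subject_id"].nunique() - len(levels) + 1
                f_p = float(sps.f.sf(f_stat, len(sel), max(df2, 1)))
            except np.linalg.LinAlgError:
                pass

        resid = np.asarray(res_final.resid)
        shapiro_p = float(sps.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan

        posthoc = self._posthoc(res_add, levels)
        return LesionModelResult(
            lambda2=lam2,
            omnibus_p=omnibus_p,
            f_stat=f_stat,
            f_p=f_p,
            interaction_lr=inter_lr,
            interaction_p=inter_p,
            used_interaction=used_inter,
            posthoc=posthoc,
            shapiro_p=shapiro_p,
            means=data.groupby("lesion_status")["value"].mean(),
            n_obs=len(data),
            n_subjects=data["subject_id"].nunique(),
        )

    def _posthoc(self, res, levels: list[str]) -> pd.DataFrame:
        """Pairwise status mean separation, studentized-range (Tukey) adjusted."""
        names = list(res.params.index)
        k = len(levels)
        df_err = max(self.data["subject_id"].nunique() - k + 1, 2)

        def coef_vector(level: str) -> np.ndarray:
            v = np.zeros(len(names))
            for i, nm in enumerate(names):
                if f"lesion_status)[T.{level}]" in nm:
                    v[i] = 1.0
            return v

        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        rows = []
        for a in range(k):
            for b in range(a + 1, k):
                c = coef_vector(levels[b]) - coef_vector(levels[a])
                est = float(c @ res.params.values[: len(names)]) * self._scale
                se = float(np.sqrt(c @ cov @ c)) * self._scale
                t = est / se if se > 0 else 0.0
                p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, df_err))
                rows.append(
                    {
                        "contrast": f"{levels[b]} - {levels[a]}",
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "p_tukey": min(1.0, p),
                    }
                )
        return pd.DataFrame(rows)


def fit_lesion_model(
    observations: pd.DataFrame, covariates: tuple[str, ...] = ()
) -> LesionModelResult:
    """Convenience wrapper: build and fit a :class:`LesionStatusModel`."""
    return LesionStatusModel(observations, covariates=covariates).fit()


# ---------------------------------------------------------------------------
# Multi-threshold permutation correction (MTPC)
# ---------------------------------------------------------------------------

@dataclass
class MTPCResult:
    """Statistic-by-density curve with permutation-based cluster inference."""

    kappas: np.ndarray
    statistic: np.ndarray  # observed statistic per density
    a_crit: float  # (1 - alpha) quantile of the permutation max statistic
    clusters: list[tuple[int, int]]  # inclusive index ranges of supra-critical runs
    cluster_aucs: list[float]
    null_mean_auc: float  # mean supra-critical cluster AUC in permutations
    significant: bool
    n_perm: int

    @property
    def max_statistic(self) -> float:
        return float(np.max(self.statistic)) if len(self.statistic) else np.nan


def _group_f_stats(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F per column of ``values`` (vectorised)."""
    n, d = values.shape
    overall = values.mean(axis=0)
    ss_between = np.zeros(d)
    ss_within = np.zeros(d)
    for g in range(n_groups):
        sel = codes == g
        ng = sel.sum()
        if ng == 0:
            continue
        mg = values[sel].mean(axis=0)
        ss_between += ng * (mg - overall) ** 2
        ss_within += ((values[sel] - mg) ** 2).sum(axis=0)
    df1 = n_groups - 1
    df2 = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _cluster_auc(stat: np.ndarray, kappas: np.ndarray, run: tuple[int, int]) -> float:
    lo, hi = run
    if hi == lo:
        # single-density cluster: weight by half the local grid step
        step = kappas[1] - kappas[0] if len(kappas) > 1 else 1.0
        return float(stat[lo] * step / 2)
    return float(np.trapezoid(stat[lo : hi + 1], kappas[lo : hi + 1]))


def _permute_label_blocks(
    labels_by_subject: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    perm = rng.permutation(len(labels_by_subject))
    return labels_by_subject[perm]


def mtpc(
    curves: np.ndarray,
    labels: np.ndarray | list,
    subjects: np.ndarray | list,
    kappas: np.ndarray | list,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> MTPCResult:
    """Multi-threshold permutation correction over a density sweep.

    ``curves``: (n_observations, n_densities) metric values; ``labels``:
    group label per observation; ``subjects``: subject id per observation
    — subjects are the exchangeable units, each subject's observations
    (e.g. its two hemispheres) keep their curves and swap label blocks as
    a unit.  The per-density statistic is the one-way group F.
    """
    curves = np.asarray(curves, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    kappas = np.asarray(kappas, dtype=float)
    if curves.shape[1] != len(kappas):
        raise ValueError("curve grid does not match density grid")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation null")

    uniq_labels, codes = np.unique(labels, return_inverse=True)
    n_groups = len(uniq_labels)
    # observations blocked by subject, in first-appearance order
    subj_order = pd.unique(subjects)
    blocks = [np.flatnonzero(subjects == s) for s in subj_order]
    sizes = {len(b) for b in blocks}
    if len(sizes) != 1:
        raise ValueError("all subjects must contribute the same number of observations")
    block_idx = np.vstack(blocks)  # (n_subjects, obs_per_subject)
    label_blocks = codes[block_idx]  # label pattern per subject

    obs_stat = _group_f_stats(curves, codes, n_groups)

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    perm_stats = np.empty((n_perm, curves.shape[1]))
    for p in range(n_perm):
        permuted = _permute_label_blocks(label_blocks, rng)
        new_codes = np.empty_like(codes)
        new_codes[block_idx.ravel()] = permuted.ravel()
        st = _group_f_stats(curves, new_codes, n_groups)
        perm_stats[p] = st
        max_null[p] = st.max()
    a_crit = float(np.quantile(max_null, 1 - alpha))

    clusters = _clusters_from_mask(obs_stat > a_crit)
    cluster_aucs = [_cluster_auc(obs_stat, kappas, r) for r in clusters]

    null_aucs = []
    for p in range(n_perm):
        runs = _clusters_from_mask(perm_stats[p] > a_crit)
        if runs:
            null_aucs.append(max(_cluster_auc(perm_stats[p], kappas, r) for r in runs))
    null_mean_auc = float(np.mean(null_aucs)) if null_aucs else 0.0

    significant = any(auc > null_mean_auc for auc in cluster_aucs) and bool(clusters)
    return MTPCResult(
        kappas=kappas,
        statistic=obs_stat,
        a_crit=a_crit,
        clusters=clusters,
        cluster_aucs=cluster_aucs,
        null_mean_auc=null_mean_auc,
        significant=significant,
        n_perm=n_perm,
    )


def pooled_residual_mtpc(
    curves: np.ndarray,
    sides: np.ndarray | list,
    labels: np.ndarray | list,
    subjects: np.ndarray | list,
    kappas: np.ndarray | list,
    healthy_label: str = "healthy",
    **kw,
) -> MTPCResult:
    """MTPC on residuals after removing hemisphere- and density-specific
    reference averages, pooling both hemispheres.

    Residuals subtract the healthy-group mean of each (side, density)
    cell (the overall cell mean if a cell has no healthy observations),
    which removes side effects shared by all groups before the pooled
    lesion-status contrast.
    """
    curves = np.asarray(curves, dtype=float)
    sides = np.asarray(sides)
    labels = np.asarray(labels)
    resid = curves.copy()
    for side in np.unique(sides):
        sel = sides == side
        ref = sel & (labels == healthy_label)
        baseline = curves[ref].mean(axis=0) if ref.any() else curves[sel].mean(axis=0)
        resid[sel] -= baseline
    return mtpc(resid, labels, subjects, kappas, **kw)


# ---------------------------------------------------------------------------
# Mass-univariate node tests and clinical regression
# ---------------------------------------------------------------------------

def mass_univariate_nodes(
    strengths: np.ndarray,
    observations: pd.DataFrame,
    node_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region lesion-status mixed models on node strength.

    ``strengths``: (n_observations, n_nodes); ``observations``: metadata
    frame aligned row-wise (columns subject_id, side, lesion_status).
    Returns per-node omnibus p, -log10(p), and a Bonferroni flag at
    ``alpha / n_nodes``.
    """
    strengths = np.asarray(strengths, dtype=float)
    n_obs, n_nodes = strengths.shape
    if len(observations) != n_obs:
        raise ValueError("observation table does not match strength rows")
    if node_names is None:
        node_names = [f"node_{i}" for i in range(n_nodes)]
    threshold = alpha / n_nodes
    rows = []
    meta = observations[["subject_id", "side", "lesion_status"]].reset_index(drop=True)
    for j in range(n_nodes):
        df = meta.copy()
        df["value"] = strengths[:, j]
        try:
            # omnibus main effect only: the interaction refit is left to the
            # targeted follow-up analyses
            res = LesionStatusModel(df).fit(test_interaction=False)
            p = res.omnibus_p
            lam = res.lambda2
        except Exception:
            p, lam = 1.0, 0.0
        rows.append(
            {
                "node": node_names[j],
                "lambda2": lam,
                "p": p,
                "neglog10_p": -np.log10(max(p, 1e-300)),
                "significant": p < threshold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def clinical_regression(metric: np.ndarray, score: np.ndarray) -> dict[str, float]:
    """OLS of a clinical score on a connectome metric; slope, Pearson r, p."""
    metric = np.asarray(metric, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(metric) != len(score):
        raise ValueError("metric and score lengths differ")
    if len(metric) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(score) == 0 or np.var(metric) == 0:
        raise ValueError("zero variance in metric or score")
    fit = sps.linregress(metric, score)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "n": int(len(metric)),
    }
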