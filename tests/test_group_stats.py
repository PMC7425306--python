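"""Mixed-effects lesion model, MTPC, mass-univariate nodes, regressions."""

import numpy as np
import pandas as pd
import pytest

import connectolesion as cl
from connectolesion.group_stats import LesionStatusModel


def simulate_observations(
    rng,
    n_patients=17,
    n_controls=21,
    ipsi_shift=0.0,
    contra_shift=0.0,
    side_shift=0.0,
    subject_sd=0.5,
    noise_sd=1.0,
):
    rows = []
    for i in range(n_patients):
        re_ = rng.normal(0, subject_sd)
        lesion_side = "left" if i % 2 == 0 else "right"
        for side in ("left", "right"):
            st = "ipsilesional" if side == lesion_side else "contralesional"
            shift = ipsi_shift if st == "ipsilesional" else contra_shift
            rows.append(
                {
                    "subject_id": f"p{i}",
                    "side": side,
                    "lesion_status": st,
                    "value": rng.normal(shift, noise_sd)
                    + re_
                    + (side_shift if side == "left" else 0),
                }
            )
    for i in range(n_controls):
        re_ = rng.normal(0, subject_sd)
        for side in ("left", "right"):
            rows.append(
                {
                    "subject_id": f"c{i}",
                    "side": side,
                    "lesion_status": "healthy",
                    "value": rng.normal(0, noise_sd)
                    + re_
                    + (side_shift if side == "left" else 0),
                }
            )
    return pd.DataFrame(rows)


class TestLesionModel:
    def test_planted_deficit_recovered_with_posthoc_separation(self):
        """A 2-within-subject-SD ipsilesional deficit is separated from both
        other levels in at least 90% of seeded cohorts, and the estimated
        effect is within 2 SE of truth in at least 95%."""
        hits, covered = 0, 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            df = simulate_observations(rng, ipsi_shift=-2.0, noise_sd=1.0)
            res = cl.fit_lesion_model(df)
            ph = res.posthoc.set_index("contrast")
            sep = (
                ph.loc["ipsilesional - healthy", "p_tukey"] < 0.05
                and ph.loc["ipsilesional - contralesional", "p_tukey"] < 0.05
            )
            hits += sep
            est = ph.loc["ipsilesional - healthy", "estimate"]
            se = ph.loc["ipsilesional - healthy", "se"]
            covered += abs(est - (-2.0)) < 2 * se
        assert hits / n_rep >= 0.9
        assert covered / n_rep >= 0.95

    def test_omnibus_reports_both_lr_and_f(self):
        rng = np.random.default_rng(0)
        res = cl.fit_lesion_model(simulate_observations(rng, ipsi_shift=-1.0))
        assert res.lambda2 > 0
        assert np.isfinite(res.f_stat)
        assert 0 <= res.omnibus_p <= 1

    def test_degenerate_constant_response(self):
        rng = np.random.default_rng(0)
        df = simulate_observations(rng)
        df["value"] = 3.14
        with pytest.warns(UserWarning):
            res = cl.fit_lesion_model(df)
        assert res.degenerate
        assert res.lambda2 == 0.0

    def test_requires_two_status_levels(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "side": ["left", "right"] * 2,
                "lesion_status": ["healthy"] * 4,
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError):
            LesionStatusModel(df)

    def test_covariates_accepted(self):
        rng = np.random.default_rng(2)
        df = simulate_observations(rng, ipsi_shift=-1.0)
        ages = {s: rng.uniform(50, 80) for s in df["subject_id"].unique()}
        df["age"] = df["subject_id"].map(ages)
        res = LesionStatusModel(df, covariates=("age",)).fit()
        assert 0 <= res.omnibus_p <= 1


class TestMTPC:
    def grid(self):
        return np.asarray(cl.sweep_kappas())

    def test_constant_curves_no_cluster(self):
        rng = np.random.default_rng(3)
        df = simulate_observations(rng)
        curves = np.ones((len(df), 13))
        res = cl.mtpc(
            curves, df["lesion_status"], df["subject_id"], self.grid(),
            n_perm=200, seed=0,
        )
        assert res.clusters == []
        assert not res.significant

    def test_planted_shift_spans_full_grid(self):
        rng = np.random.default_rng(4)
        df = simulate_observations(rng)
        curves = rng.normal(0, 1, (len(df), 13))
        curves[(df["lesion_status"] == "ipsilesional").to_numpy()] -= 2.0
        res = cl.mtpc(
            curves, df["lesion_status"], df["subject_id"], self.grid(),
            n_perm=300, seed=1,
        )
        assert res.significant
        assert res.clusters == [(0, 12)]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        df = simulate_observations(rng)
        curves = rng.normal(0, 1, (len(df), 13))
        a = cl.mtpc(curves, df["lesion_status"], df["subject_id"], self.grid(),
                    n_perm=150, seed=7)
        b = cl.mtpc(curves, df["lesion_status"], df["subject_id"], self.grid(),
                    n_perm=150, seed=7)
        assert a.a_crit == b.a_crit
        np.testing.assert_array_equal(a.statistic, b.statistic)

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(6)
        df = simulate_observations(rng, n_patients=4, n_controls=4)
        curves = rng.normal(0, 1, (len(df), 13))
        with pytest.warns(UserWarning):
            cl.mtpc(curves, df["lesion_status"], df["subject_id"], self.grid(),
                    n_perm=50, seed=0)

    def test_mtpc_no_more_liberal_than_bonferroni_scan(self):
        """Family-wise, MTPC must not reject more often than a per-density
        Bonferroni-corrected F scan on shared null datasets."""
        grid = self.grid()
        mtpc_rej, bonf_rej = 0, 0
        from connectolesion.group_stats import _group_f_stats
        from scipy import stats as sps

        for s in range(50):
            rng = np.random.default_rng(2000 + s)
            df = simulate_observations(rng, subject_sd=0.0)
            curves = rng.normal(0, 1, (len(df), 13))
            res = cl.mtpc(curves, df["lesion_status"], df["subject_id"], grid,
                          n_perm=200, seed=s)
            mtpc_rej += res.significant
            _, codes = np.unique(df["lesion_status"], return_inverse=True)
            f = _group_f_stats(curves, codes, 3)
            pvals = sps.f.sf(f, 2, len(df) - 3)
            bonf_rej += (pvals < 0.05 / 13).any()
        assert mtpc_rej <= bonf_rej + 2  # allow tiny Monte-Carlo slack


class TestPooledResidualMTPC:
    def test_side_only_effect_removed(self):
        rng = np.random.default_rng(8)
        df = simulate_observations(rng, side_shift=3.0, subject_sd=0.2)
        curves = rng.normal(0, 1, (len(df), 13)) + 3.0 * (
            df["side"] == "left"
        ).to_numpy()[:, None]
        res = cl.pooled_residual_mtpc(
            curves, df["side"], df["lesion_status"], df["subject_id"],
            cl.sweep_kappas(), n_perm=200, seed=0,
        )
        assert not res.significant

    def test_bilateral_lesion_effect_detected(self):
        rng = np.random.default_rng(9)
        df = simulate_observations(rng, subject_sd=0.2)
        shift = np.where(df["lesion_status"] == "healthy", 0.0, -1.5)
        curves = rng.normal(0, 1, (len(df), 13)) + shift[:, None]
        res = cl.pooled_residual_mtpc(
            curves, df["side"], df["lesion_status"], df["subject_id"],
            cl.sweep_kappas(), n_perm=300, seed=1,
        )
        assert res.significant

    def test_identical_hemispheres_equals_plain_mtpc_after_centering(self):
        rng = np.random.default_rng(10)
        df = simulate_observations(rng)
        curves = rng.normal(0, 1, (len(df), 13))
        # make both sides share one distribution: residualizing against the
        # healthy baseline leaves the group contrast unchanged
        plain = cl.mtpc(
            curves - curves[(df["lesion_status"] == "healthy").to_numpy()].mean(0),
            df["lesion_status"], df["subject_id"], cl.sweep_kappas(),
            n_perm=150, seed=3,
        )
        pooled = cl.pooled_residual_mtpc(
            np.where(
                (df["side"] == "left").to_numpy()[:, None], curves, curves
            ),
            np.full(len(df), "left"),
            df["lesion_status"], df["subject_id"], cl.sweep_kappas(),
            n_perm=150, seed=3,
        )
        np.testing.assert_allclose(plain.statistic, pooled.statistic, rtol=1e-10)


class TestMassUnivariate:
    def test_planted_single_node_specificity(self):
        """A deficit planted at one node flags that node and, typically,
        nothing else."""
        rng = np.random.default_rng(11)
        df = simulate_observations(rng, subject_sd=0.2)
        strengths = rng.normal(10, 1, (len(df), 41))
        target = 13
        strengths[(df["lesion_status"] == "ipsilesional").to_numpy(), target] -= 4.0
        table = cl.mass_univariate_nodes(strengths, df)
        assert table.loc[target, "significant"]
        assert table["significant"].sum() <= 3

    def test_bonferroni_threshold_recorded(self):
        rng = np.random.default_rng(12)
        df = simulate_observations(rng, n_patients=5, n_controls=5)
        strengths = rng.normal(0, 1, (len(df), 10))
        table = cl.mass_univariate_nodes(strengths, df)
        assert table.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 10)
        assert len(table) == 10


class TestClinicalRegression:
    def test_perfect_linear_relation(self):
        metric = np.array([1.0, 2.0, 3.0, 4.0])
        res = cl.clinical_regression(metric, 2 * metric)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r"] == pytest.approx(1.0)

    def test_calibrated_under_independence(self):
        rng = np.random.default_rng(13)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            res = cl.clinical_regression(rng.normal(size=17), rng.normal(size=17))
            rej += res["p"] < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            cl.clinical_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            cl.clinical_regression([1.0, 2.0], [1.0, 2.0])
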