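"""Outlier fences, mixed model/BLUPs/heritability, HSD, VIF, clustering."""

import numpy as np
import pandas as pd
import pytest

from rootscape.pheno_stats import (
    THIRTEEN_TRAITS,
    RootTraitModel,
    VarianceComponents,
    heritability,
    phenotype_clusters,
    remove_outliers,
    trait_correlation_cluster,
    tukey_hsd,
    vif,
)
from rootscape.synthetic import SyntheticStudyConfig, simulate_phenotypes


class TestRemoveOutliers:
    def test_tukey_fences_drop_extreme_value(self):
        table = pd.DataFrame(
            {"day": [9] * 5, "genotype": list("abcde"),
             "x": [1.0, 2.0, 3.0, 4.0, 100.0]}
        )
        out, report = remove_outliers(table, traits=["x"])
        assert report["removed"].sum() == 1
        assert out["x"].notna().sum() == 4
        assert np.isnan(out.loc[4, "x"])

    def test_equal_values_keep_everything(self):
        table = pd.DataFrame({"day": [9] * 6, "x": [7.0] * 6})
        out, report = remove_outliers(table, traits=["x"])
        assert report["removed"].sum() == 0
        assert out["x"].notna().all()

    def test_small_stratum_skipped_with_warning(self):
        table = pd.DataFrame({"day": [9, 9], "x": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="fences skipped"):
            out, report = remove_outliers(table, traits=["x"])
        assert out["x"].notna().all()


class TestMixedModel:
    def test_no_genetic_signal_gives_flat_blups(self):
        cfg = SyntheticStudyConfig(
            n_genotypes=40, n_replicates=10, days=(9,),
            mu=7.0, sigma_g2=0.0, sigma_b2=0.0, sigma_e2=1.0, seed=0,
        )
        table, _ = simulate_phenotypes(cfg)
        res = RootTraitModel(table, "value", day=9).fit()
        assert res.variance_components.sigma_g2 < 0.05
        assert res.blups.std() < 0.2
        assert res.blups.mean() == pytest.approx(7.0, abs=0.1)

    def test_balanced_shrinkage_closed_form(self):
        """BLUP deviations are the genotype-mean deviations shrunk by
        sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)."""
        cfg = SyntheticStudyConfig(
            n_genotypes=30, n_replicates=14, days=(9,),
            sigma_g2=1.0, sigma_b2=0.0, sigma_e2=2.0, n_blocks=1, seed=7,
        )
        table, _ = simulate_phenotypes(cfg)
        res = RootTraitModel(table, "value", day=9).fit()
        vc = res.variance_components
        shrink = vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2 / 14)
        means = table.groupby("genotype")["value"].mean()
        expected = vc.mu + shrink * (means - means.mean())
        diff = (res.blups - expected.reindex(res.blups.index)).abs().max()
        assert diff < 1e-8

    def test_variance_recovery_over_seeds(self):
        """sigma_g^2 = 1, sigma_e^2 = 2 recovered within 15% over 20 seeds."""
        sg, se = [], []
        for seed in range(20):
            cfg = SyntheticStudyConfig(
                n_genotypes=292, n_replicates=14, days=(9,),
                sigma_g2=1.0, sigma_b2=0.0, sigma_e2=2.0, seed=seed,
            )
            table, _ = simulate_phenotypes(cfg)
            vc = RootTraitModel(table, "value", day=9).fit().variance_components
            sg.append(vc.sigma_g2)
            se.append(vc.sigma_e2)
        assert np.mean(sg) == pytest.approx(1.0, rel=0.15)
        assert np.mean(se) == pytest.approx(2.0, rel=0.15)

    def test_agrees_with_reml_oracle(self):
        """Henderson-III on balanced data equals statsmodels MixedLM REML."""
        import statsmodels.formula.api as smf

        cfg = SyntheticStudyConfig(
            n_genotypes=25, n_replicates=4, days=(9,),
            sigma_g2=1.5, sigma_b2=0.0, sigma_e2=1.0, n_blocks=1, seed=3,
        )
        table, _ = simulate_phenotypes(cfg)
        ours = RootTraitModel(table, "value", day=9).fit().variance_components

        md = smf.mixedlm("value ~ 1", table, groups=table["genotype"])
        fit = md.fit(reml=True)
        assert ours.sigma_g2 == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert ours.sigma_e2 == pytest.approx(float(fit.scale), rel=1e-3)

    def test_block_variance_recovered(self):
        cfg = SyntheticStudyConfig(
            n_genotypes=200, n_replicates=14, days=(9,),
            sigma_g2=1.0, sigma_b2=4.0, sigma_e2=1.0, n_blocks=7, seed=5,
        )
        table, _ = simulate_phenotypes(cfg)
        vc = RootTraitModel(table, "value", day=9).fit().variance_components
        assert vc.sigma_b2 > 0.5  # few blocks: wide sampling spread

    def test_too_few_replicates_rejected(self):
        table = pd.DataFrame(
            {"genotype": ["a", "b"], "day": [9, 9], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="2 genotypes with >= 2"):
            RootTraitModel(table, "value", day=9)

    def test_summary_mentions_components(self):
        cfg = SyntheticStudyConfig(n_genotypes=10, n_replicates=4, days=(9,))
        table, _ = simulate_phenotypes(cfg)
        text = RootTraitModel(table, "value", day=9).fit().summary()
        assert "sigma_g^2" in text and "H^2" in text


class TestHeritability:
    def test_limits_and_substitution(self):
        assert heritability(
            VarianceComponents(1.0, 0.0, 0.0, 0.0), r=5
        ) == pytest.approx(1.0)
        assert heritability(
            VarianceComponents(1.0, 0.0, 14.0, 0.0), r=14
        ) == pytest.approx(0.5)

    def test_increasing_in_replications(self):
        vc = VarianceComponents(1.0, 0.0, 2.0, 0.0)
        values = [heritability(vc, r) for r in (1, 2, 5, 14, 50)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_undefined_when_denominator_zero(self):
        assert np.isnan(heritability(VarianceComponents(0.0, 0.0, 0.0, 0.0), 5))


class TestTukeyHSD:
    def test_threshold_formula(self):
        """q sqrt(MSE/2 (1/S + 1/S')) with q=4, MSE=9, S=S'=8 gives 4.243."""
        expected = 4.0 * np.sqrt(0.5 * 9.0 * (1 / 8 + 1 / 8))
        assert expected == pytest.approx(4.243, abs=1e-3)
        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 3, 8), rng.normal(0, 3, 8)]
        comp = tukey_hsd(groups)
        manual = comp.q * np.sqrt(0.5 * comp.mse * (1 / 8 + 1 / 8))
        assert comp.hsd.iloc[0, 1] == pytest.approx(manual)

    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        comp = tukey_hsd([g, g.copy(), g.copy()])
        assert not comp.significant.to_numpy().any()

    def test_huge_separation_is_significant(self):
        rng = np.random.default_rng(1)
        comp = tukey_hsd([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        assert comp.significant.iloc[0, 1]

    def test_threshold_shrinks_with_group_size(self):
        rng = np.random.default_rng(2)
        small = tukey_hsd([rng.normal(0, 1, 5), rng.normal(0, 1, 5)])
        big = tukey_hsd([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        assert big.hsd.iloc[0, 1] < small.hsd.iloc[0, 1]


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        report = vif(X)
        assert np.allclose(report.vif, 1.0, atol=1e-9)
        assert not report.flagged.any()

    def test_r_squared_08_gives_vif_5(self):
        """A predictor built with exactly R^2 = 0.8 on the others."""
        rng = np.random.default_rng(3)
        u = rng.normal(size=100)
        w = rng.normal(size=100)
        u = (u - u.mean()) / np.linalg.norm(u - u.mean())
        w = w - w.mean()
        w = w - (w @ u) * u  # orthogonalize
        w /= np.linalg.norm(w)
        X = pd.DataFrame({"x1": u, "x2": np.sqrt(0.8) * u + np.sqrt(0.2) * w})
        report = vif(X)
        assert report.r_squared["x2"] == pytest.approx(0.8, abs=1e-9)
        assert report.vif["x2"] == pytest.approx(5.0, abs=1e-6)

    def test_duplicated_column_reports_infinite_vif(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["dup"] = X["a"]
        report = vif(X)
        assert np.isinf(report.vif["dup"])
        assert report.flagged["dup"]


class TestTraitCorrelation:
    def test_duplicated_trait_merges_first(self):
        rng = np.random.default_rng(5)
        blups = pd.DataFrame(rng.normal(size=(40, 3)), columns=["t1", "t2", "t3"])
        blups["t1_copy"] = blups["t1"]
        corr, Z, _ = trait_correlation_cluster(blups)
        assert corr.loc["t1", "t1_copy"] == pytest.approx(1.0)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge distance

    def test_independent_traits_weakly_correlated(self):
        rng = np.random.default_rng(6)
        blups = pd.DataFrame(
            rng.normal(size=(292, 6)), columns=[f"t{i}" for i in range(6)]
        )
        corr, _, intensity = trait_correlation_cluster(blups)
        off = corr.to_numpy()[np.triu_indices(6, 1)]
        assert np.abs(off).mean() < 0.15
        assert intensity == pytest.approx(np.abs(off).sum())

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        blups = pd.DataFrame(rng.normal(size=(30, 4)))
        corr, _, _ = trait_correlation_cluster(blups)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_variance_trait_excluded(self):
        rng = np.random.default_rng(8)
        blups = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        blups["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _, _ = trait_correlation_cluster(blups)
        assert "flat" not in corr.columns


def _blup_frame(rng, n, offset=0.0, index_start=0):
    data = rng.normal(size=(n, len(THIRTEEN_TRAITS))) + offset
    return pd.DataFrame(
        data,
        columns=list(THIRTEEN_TRAITS),
        index=[f"G{index_start + i}" for i in range(n)],
    )


class TestPhenotypeClusters:
    def test_two_blobs_high_values_labeled_a(self):
        rng = np.random.default_rng(9)
        low = _blup_frame(rng, 10, offset=0.0)
        high = _blup_frame(rng, 10, offset=8.0, index_start=10)
        blups = pd.concat([low, high])
        assignment = phenotype_clusters(blups, k=2)
        assert set(assignment.labels[high.index]) == {"A"}
        assert set(assignment.labels[low.index]) == {"B"}

    def test_labels_are_a_partition(self):
        rng = np.random.default_rng(10)
        blups = _blup_frame(rng, 40)
        assignment = phenotype_clusters(blups, k=8)
        assert len(assignment.labels) == 40
        assert assignment.labels.notna().all()
        assert assignment.k == 8

    def test_cluster_mean_zscores_decrease_a_to_h(self):
        rng = np.random.default_rng(11)
        blups = _blup_frame(rng, 60)
        assignment = phenotype_clusters(blups, k=8)
        z = (blups - blups.mean()) / blups.std(ddof=1)
        means = z.mean(axis=1).groupby(assignment.labels).mean()
        ordered = means[sorted(means.index)]
        assert (ordered.diff().dropna() <= 1e-12).all()

    def test_invariant_to_trait_scaling(self):
        rng = np.random.default_rng(12)
        blups = _blup_frame(rng, 30)
        scaled = blups.copy()
        scaled["TRL"] *= 10.0
        a1 = phenotype_clusters(blups, k=4)
        a2 = phenotype_clusters(scaled, k=4)
        assert (a1.labels == a2.labels).all()

    def test_missing_trait_named_in_error(self):
        rng = np.random.default_rng(13)
        blups = _blup_frame(rng, 20).drop(columns=["RHZO"])
        with pytest.raises(KeyError, match="RHZO"):
            phenotype_clusters(blups, k=4)

    def test_k_larger_than_panel_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="exceeds"):
            phenotype_clusters(_blup_frame(rng, 5), k=8)
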